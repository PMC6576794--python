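"""Surprisal (maximum-entropy) analysis of a kinetic bulk expression matrix.

The log-expression of transcript i at time t is decomposed into a
time-invariant global steady state and a small number of time-dependent
constraints::

    ln X_i(t) = -lambda_0(t) G_i0 - sum_j lambda_j(t) G_ij

The steady state is the maximum-entropy baseline the transcriptome would
occupy with no constraints acting; each constraint j couples a
time-dependent amplitude lambda_j(t) to a time-independent, unit-norm gene
pattern G_ij.  The factorization is computed by singular value
decomposition of the ln-expression matrix: pattern columns are the left
singular vectors and each singular value is absorbed into its amplitude
series, so the patterns stay time-independent and all time dependence lives
in the amplitudes.

Sign conventions (the SVD sign is arbitrary): the baseline component is
oriented so that the mean of lambda_0(t) is positive; every constraint is
oriented so that the gene with the largest absolute loading has a positive
loading.  Repeated fits of identical input are therefore bit-identical.

The derived free-energy-like potentials are::

    f_i(t) = sum_{j>=1} lambda_j(t) G_ij          (per transcript)
    F(t)   = sum_i X_i(t) f_i(t)
           = sum_{j>=1} lambda_j(t) <G_j>(t),  <G_j>(t) = sum_i X_i(t) G_ij

F(t) scores the relative stability of the population transcriptome at time
t with respect to the global steady state; the expression weights X_i are
taken at the same timepoint as the amplitudes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SurprisalDecomposition",
    "FreeEnergySeries",
    "filter_genes",
    "fit_surprisal",
    "reconstruct",
    "steady_state_expression",
    "free_energy",
]


@dataclass
class ExpressionMatrix:
    """Positive gene x timepoint expression values (FPKM-like units)."""

    values: np.ndarray  # (n_genes, n_timepoints)
    gene_ids: list
    timepoints: np.ndarray  # days
    timepoint_labels: list | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.gene_ids = list(self.gene_ids)
        if self.values.shape != (len(self.gene_ids), self.timepoints.size):
            raise ValueError("values must be (n_genes, n_timepoints)")
        if self.timepoints.size < 2:
            raise ValueError("at least two timepoints are required")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene ids must be unique")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite and nonnegative")
        if self.timepoint_labels is None:
            self.timepoint_labels = [f"D{t:g}" for t in self.timepoints]

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.timepoint_labels)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="gene")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        labels = [str(c) for c in df.columns]
        times = []
        for lab in labels:
            m = re.search(r"[-+]?\d+(\.\d+)?", lab)
            times.append(float(m.group()) if m else float(len(times)))
        return cls(values=df.to_numpy(dtype=float), gene_ids=list(df.index),
                   timepoints=np.array(times), timepoint_labels=labels)

    @classmethod
    def from_tsv(cls, path, sep: str = "\t") -> "ExpressionMatrix":
        df = pd.read_csv(path, sep=sep, index_col=0)
        return cls.from_frame(df)


@dataclass
class SurprisalDecomposition:
    """Result of the maximum-entropy factorization of ln X.

    ``lambda_series`` holds all amplitude series (rows j = 0..r-1, columns
    timepoints); ``G`` the corresponding orthonormal gene patterns; ``J``
    is the number of *retained* constraints (the components beyond J are
    kept so that the full reconstruction identity can be checked).
    ``residual`` is ln X minus the retained reconstruction.
    """

    lambda_series: np.ndarray  # (r, n_timepoints)
    G: np.ndarray  # (n_genes, r)
    J: int
    residual: np.ndarray
    gene_ids: list
    timepoints: np.ndarray
    pseudocount: float = 0.0

    @property
    def lambda0(self) -> np.ndarray:
        """Amplitude of the global steady state per timepoint."""
        return self.lambda_series[0]

    @property
    def n_components(self) -> int:
        return self.lambda_series.shape[0]

    def amplitudes_frame(self) -> pd.DataFrame:
        idx = ["lambda0"] + [f"lambda{j}" for j in range(1, self.n_components)]
        return pd.DataFrame(self.lambda_series, index=idx,
                            columns=[f"D{t:g}" for t in self.timepoints])

    def loadings_frame(self) -> pd.DataFrame:
        cols = ["G0"] + [f"G{j}" for j in range(1, self.n_components)]
        return pd.DataFrame(self.G, index=self.gene_ids, columns=cols)


@dataclass
class FreeEnergySeries:
    """Free-energy-like potentials relative to the global steady state."""

    F: np.ndarray  # (n_timepoints,)
    f: np.ndarray  # (n_genes, n_timepoints)
    G_expect: np.ndarray  # (J, n_timepoints)
    timepoints: np.ndarray


def filter_genes(X: ExpressionMatrix, min_mean: float = 0.5, min_cv: float = 0.15) -> ExpressionMatrix:
    """Prefilter genes by expression level and temporal variability.

    Retains genes whose row mean exceeds ``min_mean`` and whose coefficient
    of variation (sample std / mean) exceeds ``min_cv``; gene order is
    preserved.  Defaults follow the common FPKM prefilter (mean > 0.5,
    CV > 0.15).
    """
    if min_mean < 0 or min_cv < 0:
        raise ValueError("thresholds must be nonnegative")
    means = X.values.mean(axis=1)
    stds = X.values.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cvs = np.where(means > 0, stds / means, 0.0)
    keep = (means > min_mean) & (cvs > min_cv)
    if not np.any(keep):
        raise ValueError(
            f"no genes survive the filter (mean > {min_mean}, CV > {min_cv})"
        )
    return ExpressionMatrix(values=X.values[keep],
                            gene_ids=[g for g, k in zip(X.gene_ids, keep) if k],
                            timepoints=X.timepoints,
                            timepoint_labels=X.timepoint_labels)


def _log_with_pseudocount(X: ExpressionMatrix) -> tuple[np.ndarray, float]:
    vals = X.values
    pc = 0.0
    if np.any(vals == 0):
        nz = vals[vals > 0]
        if nz.size == 0:
            raise ValueError("expression matrix is identically zero")
        pc = 1e-3 * nz.min()
    return np.log(vals + pc), pc


def fit_surprisal(X: ExpressionMatrix, J="auto") -> SurprisalDecomposition:
    """Fit the surprisal decomposition of a kinetic expression matrix.

    Zeros are handled by adding a pseudocount of 1e-3 times the smallest
    nonzero value before the logarithm.  ``J`` is the number of constraints
    to retain; ``"auto"`` keeps the leading constraints whose amplitude
    range (max - min over time) exceeds 5x the median range of the trailing
    half of the spectrum, which acts as a noise floor.
    """
    L, pc = _log_with_pseudocount(X)
    U, S, Vt = np.linalg.svd(L, full_matrices=False)
    r = S.size
    G = U
    lam = -(S[:, None] * Vt)  # lambda_j(t) with the singular value absorbed

    # deterministic sign conventions
    if lam[0].mean() < 0:
        lam[0] *= -1.0
        G[:, 0] *= -1.0
    for j in range(1, r):
        i_star = int(np.argmax(np.abs(G[:, j])))
        if G[i_star, j] < 0:
            G[:, j] *= -1.0
            lam[j] *= -1.0

    if J == "auto":
        if r == 1:
            J_ret = 0
        else:
            ranges = np.ptp(lam, axis=1)[1:]
            trailing = ranges[ranges.size // 2:]
            noise = np.median(trailing) if trailing.size else 0.0
            J_ret = int(np.sum(ranges > 5.0 * noise))
    else:
        J_ret = int(J)
        if J_ret < 0 or J_ret > r - 1:
            raise ValueError(
                f"requested {J_ret} constraints but the matrix supports at most {r - 1}"
            )

    recon = -(G[:, : J_ret + 1] @ lam[: J_ret + 1])
    return SurprisalDecomposition(lambda_series=lam, G=G, J=J_ret,
                                  residual=L - recon, gene_ids=X.gene_ids,
                                  timepoints=X.timepoints, pseudocount=pc)


def reconstruct(dec: SurprisalDecomposition, k: int) -> ExpressionMatrix:
    """Expression predicted from the steady state plus the top ``k`` constraints."""
    if k < 0 or k > dec.n_components - 1:
        raise ValueError(f"k must lie in [0, {dec.n_components - 1}]")
    L = -(dec.G[:, : k + 1] @ dec.lambda_series[: k + 1])
    return ExpressionMatrix(values=np.maximum(np.exp(L) - dec.pseudocount, 0.0),
                            gene_ids=dec.gene_ids, timepoints=dec.timepoints)


def steady_state_expression(dec: SurprisalDecomposition, X: ExpressionMatrix) -> ExpressionMatrix:
    """The global steady-state level of each transcript at each timepoint.

    Obtained by stripping the retained constraint terms from the measured
    level: X_i0(t) = X_i(t) with the factor exp(-sum_j lambda_j(t) G_ij)
    removed.  Its residual time variation is bounded by the variation of
    lambda_0 plus the unretained components.
    """
    L, _ = _log_with_pseudocount(X)
    f = dec.G[:, 1: dec.J + 1] @ dec.lambda_series[1: dec.J + 1]
    return ExpressionMatrix(values=np.exp(L + f), gene_ids=X.gene_ids,
                            timepoints=X.timepoints, timepoint_labels=X.timepoint_labels)


def free_energy(dec: SurprisalDecomposition, X: ExpressionMatrix) -> FreeEnergySeries:
    """Free-energy-like potentials of transcripts and of the whole transcriptome.

    With no retained constraints F(t) is identically zero: the population
    sits at the global steady state.
    """
    Gc = dec.G[:, 1: dec.J + 1]  # (n_genes, J)
    lam = dec.lambda_series[1: dec.J + 1]  # (J, T)
    f = Gc @ lam  # (n_genes, T)
    G_expect = Gc.T @ X.values  # <G_j>(t) = sum_i X_i(t) G_ij
    F = np.einsum("jt,jt->t", lam, G_expect) if dec.J > 0 else np.zeros(X.timepoints.size)
    return FreeEnergySeries(F=F, f=f, G_expect=G_expect, timepoints=X.timepoints)
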