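"""REDUCE-style motif activity inference.

Each motif's position-specific affinity matrix (PSAM) is scored against every
promoter: the affinity of a window is the product over positions of the
relative base affinities, and a promoter's total affinity N_mg is the sum
over all windows on both strands.  Per-gene expression responses (a contrast
fold-change vector, or one column per sample of a log2 fold-change matrix)
are then regressed on the affinity matrix in a single multivariate ordinary
least-squares fit with intercept:

    y_g = C + sum_m beta_m * N_mg + eps_g

The fitted beta_m is the inferred activity of motif m; its sign is attached
to -log10(p) for display, and coefficient families can be rescaled so the
largest absolute value is 1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence as TypingSequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io_formats import Sequence
from .motif_core import PSAM, revcomp, _CODE, _encode

__all__ = [
    "ActivityFit",
    "promoter_affinity",
    "fit_activity",
    "fit_activity_matrix",
    "signed_logp",
    "rescale_coefficients",
    "reduced_model_ftest",
]

_TINY = 1e-300


@dataclass(frozen=True)
class ActivityFit:
    """One motif's fitted activity from the multivariate regression."""

    motif_id: str
    beta: float
    t_stat: float
    p: float

    @property
    def signed_logp(self) -> float:
        return signed_logp(self)


def _affinity_lookup(psam: PSAM, background: TypingSequence[float] | None) -> np.ndarray:
    """W x 5 affinity lookup: columns A,C,G,T plus the N policy column
    (background-weighted mean affinity of the position)."""
    bg = np.asarray(background if background is not None else [0.25] * 4)
    a = psam.affinities
    n_col = (a * bg).sum(axis=1, keepdims=True) / bg.sum()
    return np.hstack([a, n_col])


def _strand_affinity(codes: np.ndarray, log_table: np.ndarray) -> float:
    """Sum of window affinity products on one strand.

    Window products are accumulated in log space: the window at offset o
    scores sum_j log_table[j, codes[o + j]].
    """
    W = log_table.shape[0]
    L = len(codes)
    if L < W:
        return 0.0
    n_win = L - W + 1
    acc = np.zeros(n_win)
    for j in range(W):
        acc += log_table[j, codes[j:j + n_win]]
    return float(np.exp(acc).sum())


def _batch_strand_affinity(codes: np.ndarray, log_table: np.ndarray) -> np.ndarray:
    """Vectorized :func:`_strand_affinity` for a (genes, L) code matrix."""
    W = log_table.shape[0]
    n_win = codes.shape[1] - W + 1
    acc = np.zeros((codes.shape[0], n_win))
    for j in range(W):
        acc += log_table[j, codes[:, j:j + n_win]]
    return np.exp(acc).sum(axis=1)


def promoter_affinity(
    psams: TypingSequence[PSAM],
    promoters: Mapping[str, Sequence | str],
    background: TypingSequence[float] | None = None,
    n_policy: str = "background_mean",
) -> pd.DataFrame:
    """Genes x motifs affinity matrix: N_mg = sum over windows on both strands
    of the product of per-position affinities.

    A window position reading N contributes the background-weighted mean
    affinity of its column (``n_policy='background_mean'``) or suppresses the
    window (``'skip'``).  Promoters shorter than a PSAM score 0 for it, with
    a warning.
    """
    if n_policy not in ("background_mean", "skip"):
        raise ValueError(f"unknown N policy {n_policy!r}")
    genes = list(promoters)
    mat = np.zeros((len(genes), len(psams)))
    log_tables = []
    for psam in psams:
        table = _affinity_lookup(psam, background)
        lt = np.log(np.maximum(table, _TINY))
        if n_policy == "skip":
            lt[:, 4] = -np.inf  # any N in the window suppresses it exactly
        log_tables.append(lt)

    coded = []
    for gene in genes:
        seq = promoters[gene]
        bases = (seq.bases if isinstance(seq, Sequence) else seq).upper()
        coded.append(
            (
                _CODE[_encode(bases)].astype(np.intp),
                _CODE[_encode(revcomp(bases))].astype(np.intp),
            )
        )
    lengths = {len(f) for f, _ in coded}
    short: list[str] = []
    if len(lengths) == 1 and genes:
        fwd = np.vstack([f for f, _ in coded])
        rev = np.vstack([r for _, r in coded])
        for mi, (psam, lt) in enumerate(zip(psams, log_tables)):
            if fwd.shape[1] < psam.width:
                short.extend(f"{g}/{psam.name}" for g in genes)
                continue
            mat[:, mi] = (
                _batch_strand_affinity(fwd, lt) + _batch_strand_affinity(rev, lt)
            )
    else:
        for gi, (f, r) in enumerate(coded):
            for mi, (psam, lt) in enumerate(zip(psams, log_tables)):
                if len(f) < psam.width:
                    short.append(f"{genes[gi]}/{psam.name}")
                    continue
                mat[gi, mi] = _strand_affinity(f, lt) + _strand_affinity(r, lt)
    if short:
        warnings.warn(
            f"{len(short)} promoter/motif pairs shorter than the motif "
            f"scored 0 (e.g. {short[0]})"
        )
    return pd.DataFrame(mat, index=genes, columns=[p.name for p in psams])


def fit_activity(
    N: pd.DataFrame,
    y: pd.Series | TypingSequence[float],
) -> list[ActivityFit]:
    """Ordinary least squares of the response on all motif affinities jointly,
    with intercept.  Collinear affinity columns are dropped with a warning; a
    zero-variance response yields zero coefficients with p = 1."""
    y = pd.Series(np.asarray(y, dtype=float), index=N.index)
    if len(N) <= N.shape[1]:
        raise ValueError("need more genes than motifs")
    if N.columns.duplicated().any():
        raise ValueError("duplicated motif columns")

    X = N.to_numpy(dtype=float)
    keep = _independent_columns(X)
    dropped = [c for i, c in enumerate(N.columns) if i not in keep]
    if dropped:
        warnings.warn(f"dropping collinear motif columns: {dropped}")
    cols = [N.columns[i] for i in keep]
    design = sm.add_constant(X[:, keep], has_constant="add")

    if float(np.var(y)) == 0.0:
        warnings.warn("response has zero variance; coefficients set to 0")
        fits = [ActivityFit(c, 0.0, 0.0, 1.0) for c in cols]
    else:
        res = sm.OLS(np.asarray(y), design).fit()
        fits = [
            ActivityFit(c, float(res.params[i + 1]), float(res.tvalues[i + 1]),
                        float(res.pvalues[i + 1]))
            for i, c in enumerate(cols)
        ]
    fits += [ActivityFit(c, 0.0, 0.0, 1.0) for c in dropped]
    order = {c: i for i, c in enumerate(N.columns)}
    return sorted(fits, key=lambda f: order[f.motif_id])


def _independent_columns(X: np.ndarray) -> list[int]:
    """Greedy rank-preserving column selection (with intercept implied)."""
    keep: list[int] = []
    ones = np.ones((X.shape[0], 1))
    for j in range(X.shape[1]):
        trial = np.hstack([ones] + [X[:, keep + [j]]])
        if np.linalg.matrix_rank(trial) == trial.shape[1]:
            keep.append(j)
    return keep


def fit_activity_matrix(
    N: pd.DataFrame,
    Y: pd.DataFrame,
    rescale: bool = True,
) -> pd.DataFrame:
    """Fit every sample column of a log2 fold-change matrix independently.

    Returns a long frame (sample, motif, beta, t, p, signed_logp,
    rescaled_beta); when ``rescale`` is set each motif's coefficients are
    rescaled across samples so the largest absolute value is 1.
    """
    rows = []
    for sample in Y.columns:
        for fit in fit_activity(N, Y[sample]):
            rows.append(
                {
                    "sample": sample,
                    "motif": fit.motif_id,
                    "beta": fit.beta,
                    "t": fit.t_stat,
                    "p": fit.p,
                    "signed_logp": fit.signed_logp,
                }
            )
    df = pd.DataFrame(rows)
    if rescale:
        df["rescaled_beta"] = df.groupby("motif")["beta"].transform(
            lambda s: s if s.abs().max() == 0 else s / s.abs().max()
        )
    return df


def signed_logp(fit: ActivityFit | tuple[float, float]) -> float:
    """sign(beta) * (-log10 p); p = 0 is clamped to the smallest positive
    normal float with a warning."""
    beta, p = (fit.beta, fit.p) if isinstance(fit, ActivityFit) else fit
    if p < 0 or p > 1:
        raise ValueError("p must lie in (0, 1]")
    if p == 0:
        warnings.warn("p-value of 0 clamped")
        p = np.finfo(float).tiny
    val = -math.log10(p)
    if beta > 0:
        return val
    if beta < 0:
        return -val
    return 0.0


def rescale_coefficients(values: TypingSequence[float]) -> np.ndarray:
    """Divide a coefficient family by its maximum absolute value."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty family")
    mx = np.abs(v).max()
    if mx == 0:
        raise ValueError("all-zero family cannot be rescaled")
    return v / mx


def reduced_model_ftest(
    N: pd.DataFrame,
    y: pd.Series | TypingSequence[float],
    drop: TypingSequence[str],
) -> tuple[float, float]:
    """F-test of the full fit against the fit without the ``drop`` motifs.

    Returns (F, p); a small p means the dropped motifs carry independent
    explanatory signal.
    """
    y = np.asarray(y, dtype=float)
    full = sm.OLS(y, sm.add_constant(N.to_numpy(float), has_constant="add")).fit()
    reduced_cols = [c for c in N.columns if c not in set(drop)]
    Xr = sm.add_constant(N[reduced_cols].to_numpy(float), has_constant="add")
    reduced = sm.OLS(y, Xr).fit()
    f, p, _ = full.compare_f_test(reduced)
    return float(f), float(p)
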