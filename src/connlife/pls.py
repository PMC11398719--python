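"""Behavioral partial least squares with resampling inference.

Behavioral PLS decomposes the behaviors-by-brain-variables Pearson
correlation matrix R by singular value decomposition,

    R = U diag(S) V^T,

into latent variables (LVs): each LV pairs a behavior salience (column
of U), a brain salience (column of V) and a singular value expressing
the covariance captured.  Inference is fully resampling-based:

* permutation test - rows of Y are shuffled relative to X and the
  singular values recomputed; p = (1 + #{S_perm >= S_obs}) / (n_perm + 1);
* bootstrap ratios (BSR) - subjects resampled with replacement, each
  resampled SVD aligned to the original by an orthogonal Procrustes
  rotation of the behavior saliences; BSR = salience / bootstrap SE,
  with |BSR| >= 2 conventionally deemed reliable;
* split-half reproducibility - random half-splits refit independently;
  Z_sval and Z_svec summarize how stable singular values and brain
  saliences are across splits, compared against 2 + a permutation null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def _zscore_cols(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, float)
    sd = a.std(axis=0, ddof=1)
    return (a - a.mean(axis=0)) / sd


@dataclass
class PLSInput:
    """Subjects x brain-variables block X and subjects x behaviors Y.

    Zero-variance X columns are dropped with a warning (recorded in
    ``dropped``).  ``edge_index`` optionally maps each X column to the
    ``(region_i, region_j)`` pair it represents (edge mode).
    """

    X: np.ndarray
    Y: np.ndarray
    x_labels: list[str]
    y_labels: list[str]
    edge_index: np.ndarray | None = None
    dropped: list[str] = field(default_factory=list)

    def __post_init__(self):
        X = np.asarray(self.X, float)
        Y = np.asarray(self.Y, float)
        if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
            raise ValueError("X and Y must be 2-D with matching subject counts")
        if X.shape[0] < 3:
            raise ValueError("need at least 3 subjects")
        if np.isnan(X).any() or np.isnan(Y).any():
            raise ValueError("missing values are not allowed")
        if len(self.x_labels) != X.shape[1] or len(self.y_labels) != Y.shape[1]:
            raise ValueError("label lengths must match matrix widths")
        keep = np.ptp(X, axis=0) > 0  # exact constancy, immune to roundoff
        if not keep.all():
            self.dropped = [l for l, k in zip(self.x_labels, keep) if not k]
            warnings.warn(
                f"dropping {len(self.dropped)} zero-variance brain variables"
            )
            X = X[:, keep]
            self.x_labels = [l for l, k in zip(self.x_labels, keep) if k]
            if self.edge_index is not None:
                self.edge_index = np.asarray(self.edge_index)[keep]
        if X.shape[1] == 0:
            raise ValueError("no brain variables left after dropping constants")
        self.X, self.Y = X, Y

    @property
    def n(self) -> int:
        return self.X.shape[0]


def edge_pls_input(cset, cohort, mask: np.ndarray | None = None,
                   behaviors=("age", "fluid_intelligence")) -> PLSInput:
    """Vectorize the upper triangle of (masked) SC matrices into X."""
    n = cset.n_regions
    iu = np.triu_indices(n, k=1)
    if mask is not None:
        sel = mask[iu]
    else:
        sel = np.ones(len(iu[0]), bool)
    X = cset.sc[:, iu[0][sel], iu[1][sel]]
    labels = cset.regions["label"].tolist()
    edge_index = np.column_stack([iu[0][sel], iu[1][sel]])
    x_labels = [f"{labels[i]}--{labels[j]}" for i, j in edge_index]
    Y = cohort.table[list(behaviors)].to_numpy(float)
    return PLSInput(X, Y, x_labels, list(behaviors), edge_index=edge_index)


def metric_pls_input(metrics_df: pd.DataFrame, cohort, prefix: str,
                     behaviors=("age", "fluid_intelligence")) -> PLSInput:
    """Region-wise metric table (``ne_`` or ``le_`` columns) as X."""
    cols = [c for c in metrics_df.columns if c.startswith(prefix)]
    if not cols:
        raise ValueError(f"no columns with prefix {prefix!r}")
    df = metrics_df.set_index("id").loc[cohort.ids]
    X = df[cols].to_numpy(float)
    Y = cohort.table[list(behaviors)].to_numpy(float)
    return PLSInput(X, Y, cols, list(behaviors))


# ---------------------------------------------------------------------------
# Point estimates


@dataclass
class PLSModel:
    """Point estimates of the PLS decomposition R = U diag(S) V^T."""

    R: np.ndarray  # behaviors x brain variables
    U: np.ndarray  # behaviors x k
    S: np.ndarray  # k, descending
    V: np.ndarray  # brain variables x k
    brain_scores: np.ndarray  # subjects x k (standardized X projected on V)
    behavior_scores: np.ndarray  # subjects x k
    lv_behavior_corr: np.ndarray  # k x behaviors: corr(brain score, behavior)
    x_labels: list[str]
    y_labels: list[str]
    n: int

    @property
    def n_lv(self) -> int:
        return len(self.S)


def _cross_corr(Xz: np.ndarray, Yz: np.ndarray) -> np.ndarray:
    """Pearson correlation of every (behavior, brain variable) pair from
    column-standardized blocks."""
    return Yz.T @ Xz / (Xz.shape[0] - 1)


def pls_fit(inp: PLSInput) -> PLSModel:
    """SVD of the cross-block correlation matrix.

    Sign convention: each LV is oriented so its largest-magnitude
    behavior salience is positive.
    """
    if np.any(np.ptp(inp.Y, axis=0) == 0):
        const = [l for l, s in zip(inp.y_labels, np.ptp(inp.Y, axis=0))
                 if s == 0]
        raise ValueError(f"constant behavior column(s): {const}")
    Xz = _zscore_cols(inp.X)
    Yz = _zscore_cols(inp.Y)
    R = _cross_corr(Xz, Yz)
    U, S, Vt = np.linalg.svd(R, full_matrices=False)
    V = Vt.T
    for k in range(U.shape[1]):
        j = np.argmax(np.abs(U[:, k]))
        if U[j, k] < 0:
            U[:, k] *= -1
            V[:, k] *= -1
    brain_scores = Xz @ V
    behavior_scores = Yz @ U
    k = S.shape[0]
    corr = np.empty((k, Yz.shape[1]))
    for a in range(k):
        bs = brain_scores[:, a]
        bsz = (bs - bs.mean()) / bs.std(ddof=1) if bs.std(ddof=1) > 0 else bs * 0
        corr[a] = bsz @ Yz / (inp.n - 1)
    return PLSModel(R, U, S, V, brain_scores, behavior_scores, corr,
                    list(inp.x_labels), list(inp.y_labels), inp.n)


# ---------------------------------------------------------------------------
# Permutation test


@dataclass
class PermutationResult:
    p: np.ndarray  # per LV
    null_svals: np.ndarray  # n_perm x k
    n_perm: int


def permutation_test(inp: PLSInput, model: PLSModel, n_perm: int = 1000,
                     seed=None) -> PermutationResult:
    """Shuffle rows of Y relative to X; p_k = (1 + #{S*_k >= S_k}) / (n_perm + 1)."""
    if n_perm < 19:
        raise ValueError("n_perm must be >= 19")
    rng = np.random.default_rng(seed)
    Xz = _zscore_cols(inp.X)
    Yz = _zscore_cols(inp.Y)
    k = model.n_lv
    null = np.empty((n_perm, k))
    for b in range(n_perm):
        perm = rng.permutation(inp.n)
        Rp = _cross_corr(Xz, Yz[perm])
        null[b] = np.linalg.svd(Rp, compute_uv=False)[:k]
    exceed = (null >= model.S[None, :]).sum(axis=0)
    p = (1.0 + exceed) / (n_perm + 1.0)
    return PermutationResult(p=p, null_svals=null, n_perm=n_perm)


# ---------------------------------------------------------------------------
# Bootstrap ratios


def _procrustes_rotation(U0: np.ndarray, Ub: np.ndarray) -> np.ndarray:
    """Orthogonal rotation making Ub @ rot closest to U0 in Frobenius norm."""
    P, _, Qt = np.linalg.svd(Ub.T @ U0)
    return P @ Qt


@dataclass
class BootstrapResult:
    bsr: np.ndarray  # brain variables x k
    se: np.ndarray
    corr_ci: np.ndarray  # k x behaviors x 2 (low, high)
    n_boot: int
    n_redraws: int


def bootstrap_ratios(inp: PLSInput, model: PLSModel, n_boot: int = 1000,
                     seed=None, max_redraws: int = 200) -> BootstrapResult:
    """Bootstrap SE of the brain saliences, Procrustes-aligned per sample.

    Each resampled SVD is aligned to the original by an orthogonal
    Procrustes rotation of the behavior saliences, applied to the
    singular-value-scaled brain saliences ``V diag(S)`` (rotating the
    scaled matrix propagates the singular values through the rotation
    and avoids the upward bootstrap bias of the top singular value).
    BSR = original scaled salience / bootstrap SE of the scaled
    salience.  Also returns percentile 95% CIs for the correlation of
    brain scores with each behavior.
    """
    if n_boot < 50:
        raise ValueError("n_boot must be >= 50")
    rng = np.random.default_rng(seed)
    n, k = inp.n, model.n_lv
    Ws = np.empty((n_boot, model.V.shape[0], k))
    corrs = np.empty((n_boot, k, inp.Y.shape[1]))
    redraws = 0
    for b in range(n_boot):
        for _ in range(max_redraws + 1):
            idx = rng.integers(0, n, n)
            Xb, Yb = inp.X[idx], inp.Y[idx]
            if np.ptp(Xb, axis=0).min() > 0 and np.ptp(Yb, axis=0).min() > 0:
                break
            redraws += 1
        else:
            raise RuntimeError("bootstrap sample kept producing constant columns")
        Xbz, Ybz = _zscore_cols(Xb), _zscore_cols(Yb)
        Rb = _cross_corr(Xbz, Ybz)
        Ub, Sb, Vbt = np.linalg.svd(Rb, full_matrices=False)
        rot = _procrustes_rotation(model.U, Ub)
        Ws[b] = (Vbt.T * Sb) @ rot
        Vb_aligned = Vbt.T @ rot
        scores = Xbz @ Vb_aligned
        ssd = scores.std(axis=0, ddof=1)
        ssd[ssd == 0] = 1.0
        sz = (scores - scores.mean(axis=0)) / ssd
        corrs[b] = sz.T @ Ybz / (n - 1)
    se = Ws.std(axis=0, ddof=1)
    W0 = model.V * model.S
    with np.errstate(divide="ignore", invalid="ignore"):
        bsr = np.where(se > 0, W0 / se, np.sign(W0) * np.inf)
    bsr = np.where((se == 0) & (W0 == 0), 0.0, bsr)
    ci = np.stack(
        [np.percentile(corrs, 2.5, axis=0), np.percentile(corrs, 97.5, axis=0)],
        axis=-1,
    )
    return BootstrapResult(bsr=bsr, se=se, corr_ci=ci, n_boot=n_boot,
                           n_redraws=redraws)


# ---------------------------------------------------------------------------
# Split-half reproducibility


def _split_similarities(Xz, Yz, S_full, rng, n_splits):
    """Per-split singular-value and singular-vector similarities.

    Singular-value similarity cross-projects each half's saliences onto
    the other half's correlation matrix, normalized by the full-data
    singular value -- near 1 for a stable LV, zero-mean under the null.
    Singular-vector similarity is the absolute correlation of matched
    brain saliences between halves.
    """
    n, k = Xz.shape[0], len(S_full)
    sval = np.empty((n_splits, k))
    svec = np.empty((n_splits, k))
    h1 = n // 2 + n % 2  # larger half takes the extra subject
    for s in range(n_splits):
        perm = rng.permutation(n)
        halves = []
        for sel in (perm[:h1], perm[h1:]):
            Xh, Yh = Xz[sel], Yz[sel]
            sd_x = Xh.std(axis=0, ddof=1)
            sd_y = Yh.std(axis=0, ddof=1)
            sd_x[np.ptp(Xh, axis=0) == 0] = 1.0
            sd_y[np.ptp(Yh, axis=0) == 0] = 1.0
            sd_x[sd_x == 0] = 1.0
            sd_y[sd_y == 0] = 1.0
            Xh = (Xh - Xh.mean(axis=0)) / sd_x
            Yh = (Yh - Yh.mean(axis=0)) / sd_y
            Rh = _cross_corr(Xh, Yh)
            Uh, Sh, Vht = np.linalg.svd(Rh, full_matrices=False)
            halves.append((Rh, Uh[:, :k], Vht.T[:, :k]))
        (R1, U1, V1), (R2, U2, V2) = halves
        cross12 = np.einsum("jk,jl,lk->k", U1, R2, V1)
        cross21 = np.einsum("jk,jl,lk->k", U2, R1, V2)
        sval[s] = (cross12 + cross21) / (2.0 * S_full)
        # greedy LV matching on |corr| between half brain saliences
        cmat = np.abs(np.corrcoef(V1.T, V2.T)[:k, k:])
        used = np.zeros(k, bool)
        for a in range(k):
            order = np.argsort(cmat[a])[::-1]
            for b in order:
                if not used[b]:
                    used[b] = True
                    svec[s, a] = cmat[a, b]
                    break
    return sval, svec


def _z_over_splits(sim: np.ndarray) -> np.ndarray:
    mean = sim.mean(axis=0)
    sd = sim.std(axis=0, ddof=1)
    sd[sd == 0] = np.finfo(float).tiny
    return mean / sd


@dataclass
class SplitHalfResult:
    z_sval: np.ndarray
    z_svec: np.ndarray
    z_sval_null: np.ndarray
    z_svec_null: np.ndarray
    n_splits: int

    @property
    def sval_threshold(self) -> np.ndarray:
        return 2.0 + self.z_sval_null

    @property
    def svec_threshold(self) -> np.ndarray:
        return 2.0 + self.z_svec_null

    @property
    def reproducible(self) -> np.ndarray:
        """LV flagged reproducible iff Z_svec clears 2 + its null Z."""
        return self.z_svec > self.svec_threshold


def split_half(inp: PLSInput, n_splits: int = 1000, seed=None,
               n_null_perm: int = 10) -> SplitHalfResult:
    """Split-half reproducibility Z statistics with permutation nulls.

    Each split halves the subjects at random and refits PLS in each half;
    singular-value similarity is the cross-half product normalized by the
    squared full-data singular value, singular-vector similarity the
    absolute correlation of matched brain saliences.  Z = mean/SD over
    splits.  Null Zs repeat the procedure on Y-permuted data
    (``n_null_perm`` permutations, averaged).
    """
    if inp.n < 8:
        raise ValueError("need at least 8 subjects for split-half")
    rng = np.random.default_rng(seed)
    Xz, Yz = _zscore_cols(inp.X), _zscore_cols(inp.Y)
    R = _cross_corr(Xz, Yz)
    S_full = np.linalg.svd(R, compute_uv=False)
    sval, svec = _split_similarities(Xz, Yz, S_full, rng, n_splits)
    z_sval, z_svec = _z_over_splits(sval), _z_over_splits(svec)

    null_sval = np.zeros_like(z_sval)
    null_svec = np.zeros_like(z_svec)
    for _ in range(n_null_perm):
        perm = rng.permutation(inp.n)
        Yp = Yz[perm]
        Sp = np.linalg.svd(_cross_corr(Xz, Yp), compute_uv=False)
        sv, se = _split_similarities(Xz, Yp, Sp, rng, n_splits)
        null_sval += _z_over_splits(sv)
        null_svec += _z_over_splits(se)
    null_sval /= n_null_perm
    null_svec /= n_null_perm
    return SplitHalfResult(z_sval=z_sval, z_svec=z_svec,
                           z_sval_null=null_sval, z_svec_null=null_svec,
                           n_splits=n_splits)


# ---------------------------------------------------------------------------
# Reliable-pattern reporting


@dataclass
class ReliablePattern:
    """Variables surviving the BSR threshold for one LV and sign."""

    lv: int
    sign: str  # positive | negative
    variables: pd.DataFrame  # label, bsr
    degree: pd.Series | None = None  # per-region degree over selected edges
    hubs: list[str] = field(default_factory=list)  # degree > 3
    pct_intra_left: float | None = None
    pct_intra_right: float | None = None
    pct_inter: float | None = None

    @property
    def pct_intra(self) -> float | None:
        if self.pct_intra_left is None:
            return None
        return self.pct_intra_left + self.pct_intra_right


def reliable_pattern(model: PLSModel, boot: BootstrapResult, lv: int,
                     bsr_threshold: float = 2.0,
                     region_metadata: pd.DataFrame | None = None,
                     edge_index: np.ndarray | None = None,
                     sign: str = "positive") -> ReliablePattern:
    """Select variables with |BSR| >= threshold of the requested sign.

    In edge mode (``edge_index`` given) also reports per-region degree
    over the selected edges, hub regions (degree > 3), and the
    intra-left / intra-right / inter-hemispheric percentage split.
    """
    if bsr_threshold <= 0:
        raise ValueError("bsr_threshold must be positive")
    bsr = boot.bsr[:, lv]
    if sign == "positive":
        sel = bsr >= bsr_threshold
    elif sign == "negative":
        sel = bsr <= -bsr_threshold
    else:
        raise ValueError("sign must be 'positive' or 'negative'")
    variables = pd.DataFrame(
        {"label": [model.x_labels[i] for i in np.flatnonzero(sel)],
         "bsr": bsr[sel]}
    )
    pat = ReliablePattern(lv=lv, sign=sign, variables=variables)
    if edge_index is not None and region_metadata is not None:
        edges = np.asarray(edge_index)[sel]
        labels = region_metadata["label"].tolist()
        hemi = region_metadata["hemisphere"].to_numpy()
        deg = np.zeros(len(labels), int)
        n_l = n_r = n_x = 0
        for i, j in edges:
            deg[i] += 1
            deg[j] += 1
            if hemi[i] == hemi[j]:
                if hemi[i] == "L":
                    n_l += 1
                else:
                    n_r += 1
            else:
                n_x += 1
        pat.degree = pd.Series(deg, index=labels)
        pat.hubs = [labels[i] for i in np.flatnonzero(deg > 3)]
        total = max(len(edges), 1)
        pat.pct_intra_left = 100.0 * n_l / total
        pat.pct_intra_right = 100.0 * n_r / total
        pat.pct_inter = 100.0 * n_x / total
    return pat


# ---------------------------------------------------------------------------
# Convenience bundle


@dataclass
class PLSAnalysis:
    model: PLSModel
    permutation: PermutationResult
    bootstrap: BootstrapResult
    split: SplitHalfResult


def pls_analysis(inp: PLSInput, n_perm: int = 1000, n_boot: int = 1000,
                 n_splits: int = 1000, seed=None,
                 n_null_perm: int = 10) -> PLSAnalysis:
    """Fit + permutation + bootstrap + split-half in one seeded call."""
    ss = np.random.SeedSequence(seed)
    s_perm, s_boot, s_split = ss.generate_state(3)
    model = pls_fit(inp)
    perm = permutation_test(inp, model, n_perm=n_perm, seed=int(s_perm))
    boot = bootstrap_ratios(inp, model, n_boot=n_boot, seed=int(s_boot))
    split = split_half(inp, n_splits=n_splits, seed=int(s_split),
                       n_null_perm=n_null_perm)
    return PLSAnalysis(model=model, permutation=perm, bootstrap=boot,
                       split=split)
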