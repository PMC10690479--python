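"""Label-free pull-down enrichment statistics.

Implements the proteomics tail of the pipeline, starting from a protein x
sample intensity matrix (iBAQ-like values, missing entries allowed):
identification filtering (>= 2 peptides and >= 3 quantification events in
at least one group), per-sample median normalization on complete cases,
log2 transform with left-shifted normal imputation of missing values, an
S0-moderated Welch t-test with a permutation-based FDR (q-values), and the
final enrichment call at log2 fold change > log2(10) = 3.322 and q < 0.05.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "filter_proteins",
    "normalize_median",
    "log2_and_impute",
    "welch_s0",
    "permutation_fdr",
    "classify_enriched",
    "volcano_table",
    "run_enrichment",
    "FC_THRESHOLD_LOG2",
]

FC_THRESHOLD_LOG2 = 3.322  # log2(10) to 3 d.p.: fold change > 10


def _group_columns(groups: dict[str, list[str]]) -> list[str]:
    cols: list[str] = []
    for g in groups.values():
        cols.extend(g)
    return cols


def filter_proteins(m: pd.DataFrame, groups: dict[str, list[str]],
                    peptides_col: str = "peptides") -> pd.DataFrame:
    """Keep proteins with >= 2 peptides and >= 3 events in some group.

    A quantification event is a non-missing intensity in a sample; the
    event requirement must be met within at least one experimental group.
    Rows flagged in optional boolean ``reverse`` / ``contaminant`` columns
    (reverse-database and common-contaminant identifications) are removed.
    """
    if peptides_col not in m.columns:
        raise ValueError(f"missing {peptides_col!r} column")
    keep = m[peptides_col] >= 2
    events_ok = pd.Series(False, index=m.index)
    for cols in groups.values():
        events_ok |= m[cols].notna().sum(axis=1) >= 3
    keep &= events_ok
    for flag in ("reverse", "contaminant"):
        if flag in m.columns:
            keep &= ~m[flag].astype(bool)
    return m.loc[keep].copy()


def normalize_median(m: pd.DataFrame, sample_cols: list[str]) -> pd.DataFrame:
    """Divide each sample by its median over complete-case proteins.

    Only proteins quantified in every sample contribute to the medians, so
    differing dropout patterns do not bias the normalization.  After the
    division every sample's complete-case median equals 1, which makes the
    pipeline exactly invariant to per-sample multiplicative scaling.
    """
    sub = m[sample_cols]
    complete = sub.notna().all(axis=1)
    if not complete.any():
        raise ValueError("no complete cases for normalization")
    med = sub.loc[complete].median(axis=0)
    if (med <= 0).any():
        raise ValueError("non-positive sample median")
    out = m.copy()
    out[sample_cols] = sub / med
    return out


def log2_and_impute(m: pd.DataFrame, sample_cols: list[str],
                    width: float = 0.3, downshift: float = 1.8,
                    seed: int = 0) -> pd.DataFrame:
    """log2-transform and fill missing values from a left-shifted normal.

    Per sample, missing entries are drawn from
    Normal(mean_s - downshift*sd_s, (width*sd_s)^2) where mean_s and sd_s
    are the observed log2 statistics of that sample — emulating the fact
    that missing proteins are predominantly low-abundance.  Deterministic
    for a fixed seed.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    rng = np.random.default_rng(seed)
    out = m.copy()
    for col in sample_cols:
        vals = m[col].to_numpy(float)
        if np.any(vals[~np.isnan(vals)] <= 0):
            raise ValueError(f"non-positive intensity in sample {col!r}")
        logv = np.log2(vals)
        obs = logv[~np.isnan(logv)]
        if len(obs) < 2:
            raise ValueError(
                f"cannot estimate imputation distribution for {col!r}: "
                f"fewer than 2 observed values")
        mu, sd = float(obs.mean()), float(obs.std(ddof=1))
        miss = np.isnan(logv)
        logv[miss] = rng.normal(mu - downshift * sd, width * sd, miss.sum())
        out[col] = logv
    return out


def welch_s0(m: pd.DataFrame, groups: dict[str, list[str]],
             s0: float = 0.1, fc_mode: str = "median") -> pd.DataFrame:
    """S0-moderated Welch statistic and log2 fold change per protein.

    t_s0 = (mean1 - mean2) / (sqrt(s1^2/n1 + s2^2/n2) + s0); the constant
    S0 damps the significance of tiny-variance, small-effect proteins.
    The fold change is the difference of group medians on the log2 scale
    (``fc_mode="mean"`` switches to the mean difference for sensitivity
    checks).  Group order: the first group in ``groups`` is the bait/tail
    condition (numerator).
    """
    if len(groups) != 2:
        raise ValueError("welch_s0 compares exactly two groups")
    (_, c1), (_, c2) = groups.items()
    if len(c1) < 2 or len(c2) < 2:
        raise ValueError("each group needs >= 2 samples")
    a = m[c1].to_numpy(float)
    b = m[c2].to_numpy(float)
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    v1, v2 = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    d = np.sqrt(v1 / a.shape[1] + v2 / b.shape[1])
    denom = d + s0
    if np.any(denom == 0):
        raise ValueError("undefined statistic: zero variance with s0 = 0")
    t = (m1 - m2) / denom
    if fc_mode == "median":
        fc = np.median(a, axis=1) - np.median(b, axis=1)
    elif fc_mode == "mean":
        fc = m1 - m2
    else:
        raise ValueError("fc_mode must be 'median' or 'mean'")
    return pd.DataFrame({"t_s0": t, "log2fc": fc}, index=m.index)


def _distinct_assignments(n1: int, n2: int, n_perm: int,
                          rng: np.random.Generator) -> list[np.ndarray]:
    """Label assignments for the permutation null.

    Assignments equivalent to the observed split — the identity and, for a
    two-group design, the whole-group swap — leave every protein's |t|
    unchanged and carry no information about the null, so they are
    excluded.  When fewer informative assignments exist than ``n_perm``,
    all are enumerated; otherwise ``n_perm`` are sampled uniformly without
    replacement.
    """
    n = n1 + n2
    observed = frozenset(range(n1))
    swap = frozenset(range(n1, n))
    all_splits = [c for c in combinations(range(n), n1)
                  if frozenset(c) not in (observed, swap)]
    if not all_splits:
        raise ValueError("no informative label permutations exist")
    if len(all_splits) <= n_perm:
        chosen = all_splits
    else:
        idx = rng.choice(len(all_splits), size=n_perm, replace=False)
        chosen = [all_splits[i] for i in sorted(idx)]
    out = []
    for c in chosen:
        g1 = np.asarray(c)
        g2 = np.asarray([i for i in range(n) if i not in set(c)])
        out.append((g1, g2))
    return out


def permutation_fdr(m: pd.DataFrame, groups: dict[str, list[str]],
                    n_perm: int = 250, s0: float = 0.1,
                    seed: int = 0) -> pd.DataFrame:
    """Permutation-based FDR q-values for the S0-moderated Welch test.

    Group labels are permuted (see ``_distinct_assignments``); for each
    threshold on |t_s0| the FDR estimate is the mean permuted count of
    statistics at or above the threshold divided by the observed count.
    A protein's q-value is the minimum FDR over thresholds at or below its
    own |t_s0|, monotonized to be non-increasing in |t_s0| and capped at 1.
    Returns columns ``t_s0``, ``log2fc``, ``q`` plus the number of
    permutations used in ``attrs``.
    """
    rng = np.random.default_rng(seed)
    obs = welch_s0(m, groups, s0=s0)
    (_, c1), (_, c2) = groups.items()
    cols = list(c1) + list(c2)
    X = m[cols].to_numpy(float)
    n1 = len(c1)

    perms = _distinct_assignments(n1, len(c2), n_perm, rng)
    abs_obs = np.abs(obs["t_s0"].to_numpy())
    order = np.argsort(-abs_obs)  # descending
    sorted_abs = abs_obs[order]

    perm_counts = np.zeros(len(sorted_abs))
    for g1, g2 in perms:
        a, b = X[:, g1], X[:, g2]
        d = np.sqrt(a.var(axis=1, ddof=1) / a.shape[1]
                    + b.var(axis=1, ddof=1) / b.shape[1]) + s0
        tp = np.abs((a.mean(axis=1) - b.mean(axis=1)) / d)
        # permuted count of |t| >= each observed threshold
        tp_sorted = np.sort(tp)
        perm_counts += len(tp) - np.searchsorted(tp_sorted, sorted_abs,
                                                 side="left")
    perm_mean = perm_counts / len(perms)

    k = np.arange(1, len(sorted_abs) + 1)  # observed count at each threshold
    fdr = perm_mean / k
    # q at rank k: min FDR over thresholds at or below this |t|
    q_sorted = np.minimum.accumulate(fdr[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted

    out = obs.copy()
    out["q"] = q
    out.attrs["n_permutations"] = len(perms)
    out.attrs["s0"] = s0
    return out


def classify_enriched(table: pd.DataFrame,
                      fc_threshold_log2: float = FC_THRESHOLD_LOG2,
                      q_threshold: float = 0.05) -> pd.DataFrame:
    """Flag proteins enriched at log2fc > threshold AND q < threshold.

    Both inequalities are strict: a protein at exactly the fold-change
    threshold is not called enriched.
    """
    out = table.copy()
    out["enriched"] = (out["log2fc"] > fc_threshold_log2) \
        & (out["q"] < q_threshold)
    out.attrs.update(table.attrs)
    out.attrs["fc_threshold_log2"] = fc_threshold_log2
    out.attrs["q_threshold"] = q_threshold
    return out


def volcano_table(table: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready volcano export: log2fc vs -log10 q with the enriched flag."""
    if "enriched" not in table.columns:
        table = classify_enriched(table)
    out = pd.DataFrame({
        "label": table.index,
        "log2fc": table["log2fc"].to_numpy(),
        "neg_log10_q": -np.log10(np.clip(table["q"].to_numpy(), 1e-300, 1.0)),
        "enriched": table["enriched"].to_numpy(),
    })
    return out.reset_index(drop=True)


def run_enrichment(m: pd.DataFrame, groups: dict[str, list[str]],
                   s0: float = 0.1, n_perm: int = 250,
                   fc_threshold_log2: float = FC_THRESHOLD_LOG2,
                   q_threshold: float = 0.05, width: float = 0.3,
                   downshift: float = 1.8, seed: int = 0) -> pd.DataFrame:
    """Full screen: filter, normalize, log2+impute, test, FDR, classify."""
    sample_cols = _group_columns(groups)
    f = filter_proteins(m, groups)
    f = normalize_median(f, sample_cols)
    f = log2_and_impute(f, sample_cols, width, downshift, seed)
    tab = permutation_fdr(f[sample_cols], groups, n_perm, s0, seed + 1)
    return classify_enriched(tab, fc_threshold_log2, q_threshold)
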