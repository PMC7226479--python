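"""Nonparametric group statistics for quantified markers.

The battery applied to the five-group cohort: Kruskal-Wallis across all
groups (chi-square approximation, midrank ties), pairwise Mann-Whitney
(exact for small untied samples), Fisher's exact test for 2x2 count tables,
Spearman/Kendall rank correlations for bias checks, plain fold changes of
group means, and a generic Fisher overrepresentation test with Bonferroni
correction against a user-supplied term -> protein annotation.

Continuous marker contrasts use rank tests; Fisher's exact is reserved for
categorical/detection tables (a dichotomize-at-median helper is provided for
fidelity experiments).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError

ALPHA = 0.05


@dataclass
class GroupTestResult:
    test: str                       # kruskal_wallis | mann_whitney | fisher_exact
    statistic: float
    p_value: float
    contrast: str = ""
    protein_id: str = ""
    per_group_summary: dict = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


@dataclass
class EnrichmentResult:
    term_id: str
    k_study: int
    n_study: int
    K_ref: int
    N_ref: int
    enrichment: float
    p_raw: float
    p_bonferroni: float


def _summary(groups: Mapping[str, Sequence[float]]) -> dict:
    out = {}
    for g, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        out[g] = {
            "n": int(arr.size),
            "mean": float(arr.mean()) if arr.size else float("nan"),
            "sd": float(arr.std(ddof=1)) if arr.size > 1 else float("nan"),
        }
    return out


def kruskal_wallis(
    groups: Mapping[str, Sequence[float]], protein_id: str = ""
) -> GroupTestResult:
    """Kruskal-Wallis H with midrank tie correction, chi-square p
    (df = number of groups - 1). All-identical values give H=0, p=1."""
    samples = [np.asarray(v, dtype=float) for v in groups.values()]
    if len(samples) < 2 or any(s.size == 0 for s in samples):
        raise ValidationError("need >= 2 non-empty groups")
    if sum(s.size for s in samples) < 3:
        raise ValidationError("need >= 3 total observations")
    pooled = np.concatenate(samples)
    if np.ptp(pooled) == 0:
        h, p = 0.0, 1.0
    else:
        h, p = sps.kruskal(*samples)
    return GroupTestResult(
        "kruskal_wallis", float(h), float(p),
        contrast=" vs ".join(groups), protein_id=protein_id,
        per_group_summary=_summary(groups),
    )


def mann_whitney(
    values_a: Sequence[float],
    values_b: Sequence[float],
    contrast: str = "",
    protein_id: str = "",
) -> GroupTestResult:
    """Two-sided Mann-Whitney U.

    Exact p when the smaller sample has <= 8 observations and there are no
    ties; normal approximation with tie and continuity correction otherwise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    u, p = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return GroupTestResult(
        "mann_whitney", float(u), float(min(p, 1.0)),
        contrast=contrast, protein_id=protein_id,
        per_group_summary=_summary({"a": a, "b": b}),
    )


def fisher_exact_2x2(
    table: Sequence[Sequence[int]], contrast: str = ""
) -> GroupTestResult:
    """Two-sided Fisher's exact test on a 2x2 count table (p = sum of
    hypergeometric probabilities no larger than the observed table's)."""
    arr = np.asarray(table)
    if arr.shape != (2, 2) or np.any(arr < 0) or not np.issubdtype(
        arr.dtype, np.integer
    ):
        raise ValidationError("table must be 2x2 non-negative integers")
    odds, p = sps.fisher_exact(arr, alternative="two-sided")
    return GroupTestResult("fisher_exact", float(odds), float(p),
                           contrast=contrast)


def rank_correlations(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """(Spearman rho via midranks, Kendall tau-b with tie correction)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("need equal-length vectors with n >= 3")
    rho = sps.spearmanr(x, y).statistic
    tau = sps.kendalltau(x, y).statistic
    return float(rho), float(tau)


def fold_change(mean_num: float, mean_den: float) -> float:
    """Plain ratio of group means (detected samples only)."""
    if mean_den <= 0:
        raise ValidationError("denominator group mean must be > 0")
    return float(mean_num) / float(mean_den)


def dichotomize_at_median(values: Sequence[float]) -> np.ndarray:
    """Above/at-or-below the pooled median, for Fisher-exact fidelity runs."""
    arr = np.asarray(values, dtype=float)
    return (arr > np.median(arr)).astype(int)


def bonferroni(p_values: Sequence[float]) -> np.ndarray:
    m = len(p_values)
    return np.minimum(1.0, np.asarray(p_values, dtype=float) * m)


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted p-values (optional alternative correction)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        running = min(running, p[i] * m / (rank_idx + 1))
        adj[i] = running
    return adj


def overrepresentation_test(
    study: set[str] | Sequence[str],
    reference: set[str] | Sequence[str],
    annotation: Mapping[str, set[str] | Sequence[str]],
) -> list[EnrichmentResult]:
    """One-sided Fisher (hypergeometric upper tail) enrichment per term.

    For each term: k = study genes annotated, n = study size, K = reference
    genes annotated, N = reference size; p = P(X >= k) under the
    hypergeometric null; Bonferroni over the number of tested terms.
    Results sorted by corrected then raw p.
    """
    study = set(study)
    reference = set(reference) | study
    if not annotation:
        raise ValidationError("annotation must be non-empty")
    n, N = len(study), len(reference)
    raw = []
    for term, members in annotation.items():
        members = set(members) & reference
        k = len(study & members)
        K = len(members)
        expected = n * K / N if N else 0.0
        enr = (k / expected) if expected > 0 else float("nan")
        p = float(sps.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        raw.append((term, k, K, enr, p))
    m = len(raw)
    results = [
        EnrichmentResult(term, k, n, K, N, enr, p, min(1.0, m * p))
        for term, k, K, enr, p in raw
    ]
    results.sort(key=lambda r: (r.p_bonferroni, r.p_raw, r.term_id))
    return results


# ---------------------------------------------------------------------------
# cohort-level report
# ---------------------------------------------------------------------------

def marker_values_by_group(
    quant: pd.DataFrame, manifest: pd.DataFrame, marker: str
) -> dict[str, np.ndarray]:
    """Detected concentration values (ng/mL) of one marker, keyed by group."""
    group_of = manifest.set_index("sample_id")["group"]
    sub = quant[(quant["protein_id"] == marker)
                & quant["conc_ng_ml"].notna()]
    out: dict[str, np.ndarray] = {}
    for g in sorted(manifest["group"].unique()):
        samples = group_of[group_of == g].index
        out[g] = sub[sub["sample_id"].isin(samples)]["conc_ng_ml"].to_numpy()
    return out


def compare_groups(
    quant: pd.DataFrame,
    manifest: pd.DataFrame,
    markers: Sequence[str],
    control_group: str = "G05",
    df_groups: Sequence[str] = ("G02", "G04"),
) -> dict[str, dict]:
    """Per-marker group comparison report.

    For each marker: per-group n/mean/SD of detected concentrations, the
    overall Kruskal-Wallis p, fold changes of every group mean against the
    control group, and the fetopathy-style pairwise contrasts (each DF group
    against the pooled non-DF diabetic groups, and DF-pooled vs all others,
    by Mann-Whitney). Contrasts with an empty side are skipped.
    """
    report: dict[str, dict] = {}
    non_df_diabetic = [g for g in sorted(manifest["group"].unique())
                       if g not in df_groups and g != control_group]
    for marker in markers:
        groups = marker_values_by_group(quant, manifest, marker)
        nonempty = {g: v for g, v in groups.items() if v.size > 0}
        entry: dict = {"per_group": _summary(groups)}
        if len(nonempty) >= 2:
            kw = kruskal_wallis(nonempty, protein_id=marker)
            entry["kruskal_wallis"] = {"H": kw.statistic, "p": kw.p_value}
        folds = {}
        ctrl = groups.get(control_group, np.array([]))
        if ctrl.size:
            for g, v in nonempty.items():
                if g != control_group:
                    folds[g] = fold_change(float(v.mean()),
                                           float(ctrl.mean()))
        entry["fold_change_vs_control"] = folds
        contrasts = {}
        pooled_healthy = np.concatenate(
            [groups[g] for g in non_df_diabetic if groups[g].size]
        ) if non_df_diabetic else np.array([])
        for g in df_groups:
            if groups.get(g, np.array([])).size and pooled_healthy.size:
                mw = mann_whitney(groups[g], pooled_healthy,
                                  contrast=f"{g} vs pooled non-DF diabetic")
                contrasts[f"{g}_vs_nonDF"] = {"U": mw.statistic,
                                              "p": mw.p_value}
        df_parts = [groups[g] for g in df_groups
                    if groups.get(g, np.array([])).size]
        df_pool = np.concatenate(df_parts) if df_parts else np.array([])
        rest_parts = [v for g, v in groups.items()
                      if g not in df_groups and v.size]
        rest = np.concatenate(rest_parts) if rest_parts else np.array([])
        if df_pool.size and rest.size:
            mw = mann_whitney(df_pool, rest, contrast="DF vs non-DF")
            contrasts["DF_vs_nonDF"] = {"U": mw.statistic, "p": mw.p_value}
        entry["contrasts"] = contrasts
        report[marker] = entry
    return report
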