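"""Cohort-level statistics for vessel-to-volume ratios.

Implements the analysis layer applied to a cohort of subjects with VVR
measurements: disease staging from FIB-4 and decompensation history,
three-group Kruskal-Wallis tests followed by pairwise Mann-Whitney U tests
with Bonferroni correction, percent decreases between group medians,
Spearman correlation maps against clinical biomarkers, and subgroup
analyses by clinical stage (non-ACLD / compensated ACLD / decompensated
ACLD) and FIB-4 risk category.

The public surface is the statsmodels-style pair
:class:`CohortVVRAnalysis` (model, built from two data frames) and
:class:`CohortStatsResults` (returned by ``fit()``), plus the individual
statistical primitives used by the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

#: FIB-4 threshold separating non-advanced from advanced chronic liver
#: disease; the cutoff is closed on the ACLD side (>= 1.75 -> ACLD).
FIB4_ACLD_CUTOFF = 1.75

#: FIB-4 risk categories: [0, 1.3) low, [1.3, 2.67] intermediate, (2.67, inf) high.
FIB4_LOW_CUTOFF = 1.3
FIB4_HIGH_CUTOFF = 2.67

VVR_COLUMNS = ("tvvr_pct", "hvvr_pct", "pvvr_pct")

#: biomarkers correlated with the VVRs, in display order
DEFAULT_BIOMARKERS = (
    "albumin",
    "bilirubin",
    "platelets",
    "albi",
    "meld_na",
    "fib4",
    "lsm_kpa",
    "hvpg_mmhg",
    "spleen_volume_cc",
)

GROUP_ORDER = ("control", "non-ACLD", "ACLD")
PAIRS = (("control", "non-ACLD"), ("control", "ACLD"), ("non-ACLD", "ACLD"))


@dataclass(frozen=True)
class GroupAssignment:
    group: str  # control | non-ACLD | ACLD
    acld_stage: str | None  # compensated | decompensated (ACLD only)
    fib4_category: str | None  # low | intermediate | high


def classify_stage(fib4: float | None, decompensated: bool, is_cld: bool = True) -> GroupAssignment:
    """Stage a subject from FIB-4 and decompensation history.

    CLD subjects are ACLD iff FIB-4 >= 1.75 and/or they have a history of
    hepatic decompensation; otherwise non-ACLD. Controls bypass staging.
    A CLD subject without FIB-4 and without decompensation history is
    unclassifiable (explicit error, never a silent default).
    """
    if not is_cld:
        if decompensated:
            raise ValueError("a decompensated subject cannot be a control")
        return GroupAssignment(group="control", acld_stage=None, fib4_category=None)
    if fib4 is None or not np.isfinite(fib4):
        if decompensated:
            return GroupAssignment(group="ACLD", acld_stage="decompensated", fib4_category=None)
        raise ValueError("FIB-4 missing for a CLD subject without decompensation: unclassifiable")
    if fib4 < FIB4_LOW_CUTOFF:
        category = "low"
    elif fib4 <= FIB4_HIGH_CUTOFF:
        category = "intermediate"
    else:
        category = "high"
    if fib4 >= FIB4_ACLD_CUTOFF or decompensated:
        stage = "decompensated" if decompensated else "compensated"
        return GroupAssignment(group="ACLD", acld_stage=stage, fib4_category=category)
    return GroupAssignment(group="non-ACLD", acld_stage=None, fib4_category=category)


def median_iqr(values) -> tuple[float, float, float]:
    """(median, Q1, Q3) with linear ('type 7') quartile interpolation."""
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValueError("median_iqr requires at least one finite value")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return float(med), float(q1), float(q3)


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Rank-based Kruskal-Wallis H with tie correction; p from chi-square.

    All-identical values across groups give H = 0, p = 1 (no evidence of
    any difference), rather than scipy's all-ties error.
    """
    cleaned = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size == 0 for g in cleaned):
        raise ValueError("every group must contain at least one value")
    pooled = np.concatenate(cleaned)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*cleaned)
    return float(h), float(p)


def mann_whitney_u(x, y, exact_max_n: int = 8) -> float:
    """Two-sided Mann-Whitney U p-value.

    Uses the normal approximation with tie and continuity correction;
    switches to exact enumeration automatically when both samples are
    small (n <= ``exact_max_n``) and tie-free, which doubles as an oracle
    mode in the tests.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    no_ties = np.unique(np.concatenate([x, y])).size == x.size + y.size
    method = "exact" if (x.size <= exact_max_n and y.size <= exact_max_n and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)


def bonferroni(p_raw: float, n_comparisons: int) -> float:
    """Corrected p = min(1, raw * n_comparisons)."""
    if not 0.0 <= p_raw <= 1.0:
        raise ValueError(f"raw p-value out of [0, 1]: {p_raw}")
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    return min(1.0, p_raw * n_comparisons)


def pairwise_mwu_bonferroni(
    groups: dict[str, np.ndarray],
    pairs: tuple[tuple[str, str], ...] | None = None,
) -> dict[tuple[str, str], float]:
    """Bonferroni-corrected two-sided Mann-Whitney U p per group pair.

    The correction factor is the number of pairwise comparisons (3 for the
    three-group design). A degenerate (empty) group yields NaN for its
    pairs rather than aborting the whole table.
    """
    if pairs is None:
        names = list(groups)
        pairs = tuple((a, b) for i, a in enumerate(names) for b in names[i + 1 :])
    n_pairs = len(pairs)
    out: dict[tuple[str, str], float] = {}
    for a, b in pairs:
        ga = np.asarray(groups.get(a, ()), dtype=float)
        gb = np.asarray(groups.get(b, ()), dtype=float)
        if ga.size == 0 or gb.size == 0:
            out[(a, b)] = float("nan")
            continue
        out[(a, b)] = bonferroni(mann_whitney_u(ga, gb), n_pairs)
    return out


def percent_decrease(median_ref: float, median_new: float) -> float:
    """100 * (ref - new) / ref, rounded to one decimal; positive = decrease."""
    if median_ref <= 0:
        raise ValueError("reference median must be positive")
    return round(100.0 * (median_ref - median_new) / median_ref, 1)


def spearman_map(
    vvr_table: pd.DataFrame,
    biomarker_table: pd.DataFrame,
    vvr_columns=VVR_COLUMNS,
    biomarkers=DEFAULT_BIOMARKERS,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Spearman rho and p for each VVR x biomarker pair.

    Missing biomarker values (e.g. LSM or HVPG measured only in a subset)
    are handled pairwise-complete, so each cell has its own n. No
    multiplicity correction is applied to the map. Cells with fewer than
    ``min_pairs`` complete pairs are NaN.
    Returns a tidy frame with columns vvr, biomarker, rho, p, n.
    """
    rows = []
    for v in vvr_columns:
        for b in biomarkers:
            if b not in biomarker_table.columns:
                continue
            x = pd.to_numeric(vvr_table[v], errors="coerce")
            y = pd.to_numeric(biomarker_table[b], errors="coerce")
            ok = x.notna() & y.notna()
            n = int(ok.sum())
            if n < min_pairs:
                rho, p = float("nan"), float("nan")
            else:
                rho, p = sps.spearmanr(x[ok], y[ok])
            rows.append({"vvr": v, "biomarker": b, "rho": float(rho), "p": float(p), "n": n})
    return pd.DataFrame(rows)


@dataclass
class GroupComparison:
    """KW + pairwise MWU results for one VVR across one partition."""

    vvr: str
    group_stats: dict[str, tuple[float, float, float]]  # name -> (median, q1, q3)
    group_sizes: dict[str, int]
    kw_h: float
    kw_p: float
    pairwise_p: dict[tuple[str, str], float]
    percent_decreases: dict[tuple[str, str], float]


@dataclass
class CohortStatsResults:
    """Results container for :class:`CohortVVRAnalysis`.

    Holds the three-group comparisons per VVR, the Spearman correlation
    maps (whole CLD cohort plus per-subgroup), and the subgroup analyses
    by clinical stage and FIB-4 category.
    """

    comparisons: list[GroupComparison]
    spearman: dict[str, pd.DataFrame]
    subgroup_comparisons: dict[str, list[GroupComparison]] = field(default_factory=dict)

    def comparison(self, vvr: str) -> GroupComparison:
        for c in self.comparisons:
            if c.vvr == vvr:
                return c
        raise KeyError(vvr)

    def summary(self) -> str:
        lines = ["Vessel-to-volume ratios by group", "=" * 64]
        for c in self.comparisons:
            lines.append(f"\n{c.vvr}  (Kruskal-Wallis H={c.kw_h:.2f}, p={c.kw_p:.3g})")
            for name, (med, q1, q3) in c.group_stats.items():
                lines.append(
                    f"  {name:<10s} n={c.group_sizes[name]:<4d} "
                    f"median {med:.1f} (IQR {q1:.1f}-{q3:.1f})"
                )
            for (a, b), p in c.pairwise_p.items():
                dec = c.percent_decreases.get((a, b), float("nan"))
                lines.append(f"  {a} vs {b}: decrease {dec:.1f}%, corrected p={p:.3g}")
        lines.append("\nSpearman correlations (CLD cohort)")
        lines.append("-" * 64)
        if "cld" in self.spearman:
            for _, r in self.spearman["cld"].iterrows():
                lines.append(
                    f"  {r['vvr']:<9s} x {r['biomarker']:<17s} "
                    f"rho={r['rho']:+.2f} p={r['p']:.3g} n={r['n']}"
                )
        return "\n".join(lines)

    def comparison_frame(self) -> pd.DataFrame:
        """Table-2-style tidy frame: one row per VVR x partition cell."""
        rows = []
        for c in self.comparisons:
            for name, (med, q1, q3) in c.group_stats.items():
                rows.append(
                    {
                        "vvr": c.vvr,
                        "group": name,
                        "n": c.group_sizes[name],
                        "median": med,
                        "q1": q1,
                        "q3": q3,
                        "kw_p": c.kw_p,
                    }
                )
        return pd.DataFrame(rows)


def _compare_partition(
    values: pd.Series, labels: pd.Series, order: tuple[str, ...], vvr_name: str
) -> GroupComparison:
    groups: dict[str, np.ndarray] = {}
    for name in order:
        vals = values[labels == name].dropna().to_numpy(dtype=float)
        groups[name] = vals
    present = {k: v for k, v in groups.items() if v.size > 0}
    if len(present) >= 2:
        kw_h, kw_p = kruskal_wallis(*present.values())
    else:
        kw_h, kw_p = float("nan"), float("nan")
    pairs = tuple((a, b) for i, a in enumerate(order) for b in order[i + 1 :])
    pairwise = pairwise_mwu_bonferroni(groups, pairs)
    stats_by_group = {
        name: (median_iqr(vals) if vals.size else (float("nan"),) * 3)
        for name, vals in groups.items()
    }
    decreases = {}
    for a, b in pairs:
        ref = stats_by_group[a][0]
        new = stats_by_group[b][0]
        if np.isfinite(ref) and np.isfinite(new) and ref > 0:
            decreases[(a, b)] = percent_decrease(ref, new)
        else:
            decreases[(a, b)] = float("nan")
    return GroupComparison(
        vvr=vvr_name,
        group_stats=stats_by_group,
        group_sizes={k: int(v.size) for k, v in groups.items()},
        kw_h=kw_h,
        kw_p=kw_p,
        pairwise_p=pairwise,
        percent_decreases=decreases,
    )


class CohortVVRAnalysis:
    """Model object tying a cohort table to per-subject VVR measurements.

    Parameters
    ----------
    cohort : DataFrame indexed or keyed by ``subject_id`` with a ``group``
        column (control / non-ACLD / ACLD), optional ``acld_stage`` and
        ``fib4_category`` columns (derived via :func:`classify_stage` when
        absent but ``fib4``/``decompensated`` are available), and biomarker
        columns.
    vvr : DataFrame with ``subject_id`` and the three VVR columns
        (percent of liver volume).
    """

    def __init__(
        self,
        cohort: pd.DataFrame,
        vvr: pd.DataFrame,
        biomarkers=DEFAULT_BIOMARKERS,
    ):
        merged = cohort.merge(vvr, on="subject_id", how="inner", validate="one_to_one")
        if merged.empty:
            raise ValueError("no subjects shared between cohort and VVR tables")
        if "group" not in merged.columns:
            raise ValueError("cohort table must contain a 'group' column")
        self.data = merged
        self.biomarkers = tuple(b for b in biomarkers if b in merged.columns)
        self._derive_stages()

    def _derive_stages(self) -> None:
        df = self.data
        if "acld_stage" not in df.columns or "fib4_category" not in df.columns:
            stages, cats = [], []
            for _, row in df.iterrows():
                if row["group"] == "control":
                    stages.append(None)
                    cats.append(None)
                    continue
                fib4 = row.get("fib4")
                decomp = bool(row.get("decompensated", False))
                try:
                    ga = classify_stage(fib4, decomp, is_cld=True)
                    stages.append(ga.acld_stage)
                    cats.append(ga.fib4_category)
                except ValueError:
                    stages.append(None)
                    cats.append(None)
            if "acld_stage" not in df.columns:
                df["acld_stage"] = stages
            if "fib4_category" not in df.columns:
                df["fib4_category"] = cats

    def fit(self) -> CohortStatsResults:
        df = self.data
        comparisons = [
            _compare_partition(df[v], df["group"], GROUP_ORDER, v) for v in VVR_COLUMNS
        ]
        cld = df[df["group"] != "control"]
        spearman = {"cld": spearman_map(cld, cld, biomarkers=self.biomarkers)}
        for sub in ("non-ACLD", "ACLD"):
            part = df[df["group"] == sub]
            if len(part) >= 3:
                spearman[sub] = spearman_map(part, part, biomarkers=self.biomarkers)
        results = CohortStatsResults(comparisons=comparisons, spearman=spearman)
        results.subgroup_comparisons = self._subgroup_analyses(cld)
        return results

    def _subgroup_analyses(self, cld: pd.DataFrame) -> dict[str, list[GroupComparison]]:
        out: dict[str, list[GroupComparison]] = {}
        stage_label = cld.apply(
            lambda r: "non-ACLD"
            if r["group"] == "non-ACLD"
            else ("cACLD" if r.get("acld_stage") == "compensated" else
                  ("dACLD" if r.get("acld_stage") == "decompensated" else None)),
            axis=1,
        ) if len(cld) else pd.Series(dtype=object)
        out["clinical_stage"] = [
            _compare_partition(cld[v], stage_label, ("non-ACLD", "cACLD", "dACLD"), v)
            for v in VVR_COLUMNS
        ] if len(cld) else []
        if "fib4_category" in cld.columns and len(cld):
            out["fib4_category"] = [
                _compare_partition(cld[v], cld["fib4_category"], ("low", "intermediate", "high"), v)
                for v in VVR_COLUMNS
            ]
        return out
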