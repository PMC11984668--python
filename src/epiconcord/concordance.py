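"""Within-person cross-tissue concordance statistics.

The scientific question: do epigenetic-clock estimates from different
tissues of the same person agree?  Agreement is quantified four ways:

* paired within-person differences per tissue pair (paired t-test,
  reported as mean difference ± SE with significance stars),
* Pearson correlations of age-acceleration values across tissue pairs
  (rate clocks use the pace value itself),
* partial correlations after residualizing each tissue's acceleration
  on that sample's own cell-type proportions and on control-probe
  principal components (the batch surrogate),
* intraclass correlation coefficients across tissues, all six
  classical one-way / two-way ANOVA variants.

Cohort descriptives (Table-1 style) live here too.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CellComposition, TISSUES


class ConcordanceError(ValueError):
    pass


def stars(p: float) -> str:
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _value_column(estimates: pd.DataFrame) -> pd.Series:
    """Concordance value per row: acceleration, or pace for rate clocks."""
    val = estimates["acceleration"].copy()
    is_rate = estimates["transform"] == "rate"
    val[is_rate] = estimates.loc[is_rate, "estimate"]
    return val


def person_tissue_table(
    estimates: pd.DataFrame,
    manifest: pd.DataFrame,
    clock: str,
    column: str = "auto",
) -> pd.DataFrame:
    """Wide person x tissue table of one clock's values.

    ``column`` may be "estimate", "acceleration" or "auto"
    (acceleration, falling back to the pace value for rate clocks).
    """
    sub = estimates.loc[estimates["clock"] == clock].copy()
    if sub.empty:
        raise ConcordanceError(f"no estimates for clock {clock!r}")
    if column == "auto":
        sub["value"] = _value_column(sub)
    else:
        sub["value"] = sub[column]
    meta = manifest.set_index("sample_id")
    sub["person_id"] = sub["sample_id"].map(meta["person_id"])
    sub["tissue"] = sub["sample_id"].map(meta["tissue"])
    return sub.pivot_table(
        index="person_id", columns="tissue", values="value", aggfunc="first"
    )


# ---------------------------------------------------------------------
# paired differences (Table-2 style)
# ---------------------------------------------------------------------


@dataclass
class PairwiseComparison:
    clock: str
    tissue_a: str
    tissue_b: str
    n_pairs: int
    mean_diff: float
    se: float
    t_stat: float
    df: int
    p_two_sided: float
    degenerate: bool = False

    @property
    def stars(self) -> str:
        return stars(self.p_two_sided)


def paired_differences(
    estimates: pd.DataFrame,
    manifest: pd.DataFrame,
    tissue_a: str,
    tissue_b: str,
    clock: str,
    column: str = "estimate",
) -> PairwiseComparison:
    """Paired t-test of within-person tissue_a − tissue_b differences."""
    wide = person_tissue_table(estimates, manifest, clock, column=column)
    for t in (tissue_a, tissue_b):
        if t not in wide.columns:
            raise ConcordanceError(f"no samples for tissue {t!r}")
    paired = wide[[tissue_a, tissue_b]].dropna()
    n = len(paired)
    if n < 2:
        raise ConcordanceError(
            f"{tissue_a} vs {tissue_b}: need >= 2 complete pairs, have {n}"
        )
    d = (paired[tissue_a] - paired[tissue_b]).to_numpy()
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    se = sd / np.sqrt(n)
    degenerate = False
    if se == 0.0:
        degenerate = True
        warnings.warn(
            f"{clock} {tissue_a} vs {tissue_b}: zero-variance differences",
            stacklevel=2,
        )
        t_stat = np.inf if mean != 0 else 0.0
        p = 0.0 if mean != 0 else 1.0
    else:
        t_stat = mean / se
        p = 2.0 * stats.t.sf(abs(t_stat), n - 1)
    return PairwiseComparison(
        clock=clock,
        tissue_a=tissue_a,
        tissue_b=tissue_b,
        n_pairs=n,
        mean_diff=mean,
        se=float(se),
        t_stat=float(t_stat),
        df=n - 1,
        p_two_sided=float(p),
        degenerate=degenerate,
    )


def pairwise_difference_table(
    estimates: pd.DataFrame,
    manifest: pd.DataFrame,
    clocks: Sequence[str],
    tissue_pairs: Sequence[tuple[str, str]],
    column: str = "estimate",
    min_pairs: int = 2,
) -> pd.DataFrame:
    """Tidy table of paired differences for many clocks x tissue pairs."""
    rows = []
    for clock in clocks:
        for a, b in tissue_pairs:
            try:
                cmp_ = paired_differences(
                    estimates, manifest, a, b, clock, column=column
                )
            except ConcordanceError:
                continue
            if cmp_.n_pairs < min_pairs:
                continue
            rows.append(
                {
                    "clock": clock,
                    "tissue_a": a,
                    "tissue_b": b,
                    "n_pairs": cmp_.n_pairs,
                    "mean_diff": cmp_.mean_diff,
                    "se": cmp_.se,
                    "t": cmp_.t_stat,
                    "df": cmp_.df,
                    "p": cmp_.p_two_sided,
                    "stars": cmp_.stars,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------
# correlation matrices
# ---------------------------------------------------------------------


@dataclass
class ConcordanceMatrix:
    clock: str
    kind: str  # "raw" | "partial"
    r: pd.DataFrame
    n: pd.DataFrame
    p: pd.DataFrame
    covariates: str = ""
    notes: dict = field(default_factory=dict)


def _pearson_p(r: float, n: int) -> float:
    if n < 3 or np.isnan(r):
        return np.nan
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def tissue_correlations(
    estimates: pd.DataFrame,
    manifest: pd.DataFrame,
    clock: str,
    min_pairs: int = 3,
) -> ConcordanceMatrix:
    """Within-person Pearson correlations of acceleration across tissues.

    Rate clocks correlate the pace value itself.  Cells with fewer
    than ``min_pairs`` complete pairs are left missing.
    """
    wide = person_tissue_table(estimates, manifest, clock, column="auto")
    tissues = [t for t in TISSUES if t in wide.columns]
    r = pd.DataFrame(np.nan, index=tissues, columns=tissues)
    n = pd.DataFrame(0, index=tissues, columns=tissues)
    p = pd.DataFrame(np.nan, index=tissues, columns=tissues)
    for i, a in enumerate(tissues):
        r.loc[a, a] = 1.0
        n.loc[a, a] = int(wide[a].notna().sum())
        for b in tissues[i + 1 :]:
            paired = wide[[a, b]].dropna()
            n.loc[a, b] = n.loc[b, a] = len(paired)
            if len(paired) < min_pairs:
                continue
            x, y = paired[a].to_numpy(), paired[b].to_numpy()
            if x.std() == 0 or y.std() == 0:
                continue
            rv = float(np.corrcoef(x, y)[0, 1])
            r.loc[a, b] = r.loc[b, a] = rv
            pv = _pearson_p(rv, len(paired))
            p.loc[a, b] = p.loc[b, a] = pv
    return ConcordanceMatrix(clock=clock, kind="raw", r=r, n=n, p=p)


# ---------------------------------------------------------------------
# control-probe principal components (batch surrogate)
# ---------------------------------------------------------------------


def control_probe_pcs(
    controls: pd.DataFrame, n_pcs: int
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-sample PC scores of the centered control-probe beta matrix.

    ``controls`` is probes x samples.  Returns (scores samples x PCs,
    explained-variance fractions).  Loading signs are fixed so the
    largest-magnitude loading of each component is positive.
    """
    n_samples = controls.shape[1]
    if n_pcs < 0:
        raise ConcordanceError("n_pcs must be >= 0")
    if n_pcs == 0:
        return (
            pd.DataFrame(index=controls.columns),
            pd.Series(dtype=float),
        )
    if n_samples < n_pcs + 1:
        raise ConcordanceError(f"need >= {n_pcs + 1} samples for {n_pcs} PCs")
    x = controls.to_numpy(dtype=float)
    x = x - x.mean(axis=1, keepdims=True)  # center each probe across samples
    u, s, vt = np.linalg.svd(x.T, full_matrices=False)
    # deterministic sign: largest-|loading| positive
    for c in range(vt.shape[0]):
        j = int(np.argmax(np.abs(vt[c])))
        if vt[c, j] < 0:
            vt[c] *= -1.0
            u[:, c] *= -1.0
    scores = u[:, :n_pcs] * s[:n_pcs]
    evr = s**2 / max((s**2).sum(), 1e-300)
    cols = [f"ctrlPC{i + 1}" for i in range(n_pcs)]
    return (
        pd.DataFrame(scores, index=controls.columns, columns=cols),
        pd.Series(evr[:n_pcs], index=cols),
    )


def default_n_pcs(controls: pd.DataFrame, cap: int = 10, var_target: float = 0.9) -> int:
    """Smaller of ``cap`` and the number of PCs explaining ``var_target``."""
    max_pcs = min(controls.shape[0], controls.shape[1] - 1)
    _, evr = control_probe_pcs(controls, max_pcs)
    cum = evr.cumsum()
    enough = int(np.searchsorted(cum.to_numpy(), var_target) + 1)
    return max(1, min(cap, enough, max_pcs))


# ---------------------------------------------------------------------
# partial correlations
# ---------------------------------------------------------------------


def _residualize(y: np.ndarray, covs: np.ndarray) -> tuple[np.ndarray, int, list[int]]:
    """OLS residual of y on [1, covs]; drops collinear columns.

    Collinear columns are dropped smallest-variance first.  Returns
    (residuals, n_covariates_used, dropped column indices).
    """
    n = len(y)
    keep = list(range(covs.shape[1]))
    dropped: list[int] = []
    while True:
        x = np.column_stack([np.ones(n), covs[:, keep]]) if keep else np.ones((n, 1))
        if np.linalg.matrix_rank(x) == x.shape[1] or not keep:
            break
        variances = covs[:, keep].var(axis=0)
        j = int(np.argmin(variances))
        dropped.append(keep.pop(j))
        warnings.warn("dropping collinear covariate column", stacklevel=3)
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ beta, len(keep), dropped


def partial_correlations(
    estimates: pd.DataFrame,
    manifest: pd.DataFrame,
    cellcomp: Mapping[str, CellComposition | pd.DataFrame],
    control_pcs: pd.DataFrame,
    clock: str,
    min_pairs: int = 3,
) -> ConcordanceMatrix:
    """Partial within-person correlations controlling cell composition + batch.

    Each tissue's values are residualized on that tissue's own
    cell-type proportions (one reference category dropped) plus the
    sample's control-probe PC scores, then correlated across paired
    persons.  Cells whose residual variance collapses are flagged
    degenerate and left missing.
    """
    wide = person_tissue_table(estimates, manifest, clock, column="auto")
    meta = manifest.set_index("sample_id")
    sample_of = {
        (row["person_id"], row["tissue"]): sid for sid, row in meta.iterrows()
    }
    tissues = [t for t in TISSUES if t in wide.columns]
    r = pd.DataFrame(np.nan, index=tissues, columns=tissues)
    n = pd.DataFrame(0, index=tissues, columns=tissues)
    p = pd.DataFrame(np.nan, index=tissues, columns=tissues)
    notes: dict = {}

    def covariates_for(tissue: str, persons: pd.Index) -> np.ndarray | None:
        comp = cellcomp.get(tissue)
        props = None
        if comp is not None:
            props = comp.proportions if isinstance(comp, CellComposition) else comp
        blocks = []
        sids = [sample_of[(pid, tissue)] for pid in persons]
        if props is not None:
            # drop the last cell-type column as the reference category
            blocks.append(props.loc[sids].iloc[:, :-1].to_numpy(dtype=float))
        if control_pcs is not None and control_pcs.shape[1] > 0:
            blocks.append(control_pcs.loc[sids].to_numpy(dtype=float))
        if not blocks:
            return None
        return np.column_stack(blocks)

    for i, a in enumerate(tissues):
        r.loc[a, a] = 1.0
        n.loc[a, a] = int(wide[a].notna().sum())
        for b in tissues[i + 1 :]:
            paired = wide[[a, b]].dropna()
            n.loc[a, b] = n.loc[b, a] = len(paired)
            if len(paired) < min_pairs:
                continue
            persons = paired.index
            n_cov = 0
            res = {}
            degenerate = False
            for tissue, vals in ((a, paired[a]), (b, paired[b])):
                y = vals.to_numpy(dtype=float)
                covs = covariates_for(tissue, persons)
                if covs is None:
                    res[tissue], used = y - y.mean(), 0
                else:
                    res[tissue], used, _ = _residualize(y, covs)
                n_cov = max(n_cov, used)
                if res[tissue].std() < 1e-10 * max(y.std(), 1e-300):
                    degenerate = True
            if degenerate:
                notes[(a, b)] = "degenerate: residual variance ~ 0"
                continue
            rv = float(np.corrcoef(res[a], res[b])[0, 1])
            r.loc[a, b] = r.loc[b, a] = rv
            df = len(persons) - 2 - n_cov
            if df > 0 and abs(rv) < 1.0:
                t = rv * np.sqrt(df / (1.0 - rv * rv))
                pv = float(2.0 * stats.t.sf(abs(t), df))
            elif abs(rv) >= 1.0:
                pv = 0.0
            else:
                pv = np.nan
            p.loc[a, b] = p.loc[b, a] = pv
    return ConcordanceMatrix(
        clock=clock,
        kind="partial",
        r=r,
        n=n,
        p=p,
        covariates="tissue cell proportions (reference category dropped) "
        "+ control-probe PCs",
        notes=notes,
    )


# ---------------------------------------------------------------------
# intraclass correlation
# ---------------------------------------------------------------------


@dataclass
class ICCTable:
    clock: str
    table: pd.DataFrame  # per-variant estimates with CIs
    n: int
    k: int


def icc_from_wide(wide: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """All six classical ICC variants from a complete persons x raters table.

    Rows: ICC1, ICC1k (one-way random, single/average), ICC2, ICC2k
    (two-way random), ICC3, ICC3k (two-way mixed).  Confidence bounds
    follow the standard F-based formulas.
    """
    data = wide.dropna().to_numpy(dtype=float)
    n, k = data.shape
    if n < 2 or k < 2:
        raise ConcordanceError(f"need >= 2 persons and >= 2 raters, got {n} x {k}")
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ssb = k * float(((row_means - grand) ** 2).sum())
    ssj = n * float(((col_means - grand) ** 2).sum())
    sse = float(
        ((data - row_means[:, None] - col_means[None, :] + grand) ** 2).sum()
    )
    ssw = float(((data - row_means[:, None]) ** 2).sum())
    # numpy scalars: degenerate tables (zero residual) give inf/nan
    # instead of raising
    msb = np.float64(ssb / (n - 1))
    msj = np.float64(ssj / (k - 1))
    mse = np.float64(sse / ((n - 1) * (k - 1)))
    msw = np.float64(ssw / (n * (k - 1)))

    icc1 = (msb - msw) / (msb + (k - 1) * msw)
    icc1k = (msb - msw) / msb
    icc2 = (msb - mse) / (msb + (k - 1) * mse + k * (msj - mse) / n)
    icc2k = (msb - mse) / (msb + (msj - mse) / n)
    icc3 = (msb - mse) / (msb + (k - 1) * mse)
    icc3k = (msb - mse) / msb

    q = 1 - alpha / 2
    df1, df1kd, df2kd = n - 1, n * (k - 1), (n - 1) * (k - 1)
    f1 = msb / msw
    f1l = f1 / stats.f.ppf(q, df1, df1kd)
    f1u = f1 * stats.f.ppf(q, df1kd, df1)
    f3 = msb / mse
    f3l = f3 / stats.f.ppf(q, df1, df2kd)
    f3u = f3 * stats.f.ppf(q, df2kd, df1)
    # two-way random CI (Satterthwaite df, psych-style)
    fj = msj / mse
    vn = df2kd * (k * icc2 * fj + n * (1 + (k - 1) * icc2) - k * icc2) ** 2
    vd = df1 * k**2 * icc2**2 * fj**2 + (n * (1 + (k - 1) * icc2) - k * icc2) ** 2
    v = vn / vd
    f2u = stats.f.ppf(q, n - 1, v)
    f2l = stats.f.ppf(q, v, n - 1)
    l2 = n * (msb - f2u * mse) / (
        f2u * (k * msj + (k * n - k - n) * mse) + n * msb
    )
    u2 = n * (f2l * msb - mse) / (k * msj + (k * n - k - n) * mse + n * f2l * msb)

    def sb(x: float) -> float:  # Spearman-Brown step-up
        return x * k / (1 + x * (k - 1))

    p1 = float(stats.f.sf(f1, df1, df1kd))
    p3 = float(stats.f.sf(f3, df1, df2kd))
    rows = [
        ("ICC1", "one-way random, single", icc1, (f1l - 1) / (f1l + k - 1),
         (f1u - 1) / (f1u + k - 1), f1, p1),
        ("ICC1k", "one-way random, average", icc1k, 1 - 1 / f1l, 1 - 1 / f1u, f1, p1),
        ("ICC2", "two-way random, single", icc2, l2, u2, f3, p3),
        ("ICC2k", "two-way random, average", icc2k, sb(l2), sb(u2), f3, p3),
        ("ICC3", "two-way mixed, single", icc3, (f3l - 1) / (f3l + k - 1),
         (f3u - 1) / (f3u + k - 1), f3, p3),
        ("ICC3k", "two-way mixed, average", icc3k, 1 - 1 / f3l, 1 - 1 / f3u, f3, p3),
    ]
    return pd.DataFrame(
        rows, columns=["variant", "description", "est", "ci_lower", "ci_upper", "F", "p"]
    )


def compute_icc(
    estimates: pd.DataFrame,
    manifest: pd.DataFrame,
    clock: str,
    tissues: Sequence[str] | None = None,
    column: str = "auto",
) -> ICCTable:
    """ICC of one clock across tissues, listwise-complete persons only."""
    wide = person_tissue_table(estimates, manifest, clock, column=column)
    if tissues is not None:
        missing = [t for t in tissues if t not in wide.columns]
        if missing:
            raise ConcordanceError(f"no samples for tissues {missing}")
        wide = wide[list(tissues)]
    complete = wide.dropna()
    table = icc_from_wide(complete)
    return ICCTable(clock=clock, table=table, n=len(complete), k=wide.shape[1])


# ---------------------------------------------------------------------
# cohort descriptives (Table-1 style)
# ---------------------------------------------------------------------


def pooled_mean_sd(
    ns: Sequence[int], means: Sequence[float], sds: Sequence[float]
) -> tuple[float, float]:
    """Combine stratum summary statistics into pooled mean and SD.

    Uses the exact ANOVA identity: pooled variance aggregates the
    within-stratum sums of squares and the between-stratum spread, with
    an n−1 denominator matching the sample SD convention.
    """
    ns = np.asarray(ns, dtype=float)
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    total = ns.sum()
    grand = float((ns * means).sum() / total)
    ss_within = ((ns - 1) * sds**2).sum()
    ss_between = (ns * (means - grand) ** 2).sum()
    sd = float(np.sqrt((ss_within + ss_between) / (total - 1)))
    return grand, sd


def describe_cohort(manifest: pd.DataFrame) -> pd.DataFrame:
    """Descriptive table per cohort and pooled (Table-1 layout).

    Rows: person counts, age mean/SD/range, sex counts with
    percentages, tissue counts with percentages (denominator = persons
    in the column).  Percentages are rounded to one decimal.
    """
    if manifest.empty:
        raise ConcordanceError("empty manifest")
    persons = manifest.drop_duplicates("person_id").set_index("person_id")
    groups = {"child": persons[persons["cohort"] == "child"]}
    groups["adult"] = persons[persons["cohort"] == "adult"]
    groups["total"] = persons
    tissues_present = [t for t in TISSUES if t in set(manifest["tissue"])]

    out: dict[str, dict] = {}
    for label, grp in groups.items():
        col: dict[str, float] = {"n": len(grp)}
        ages = grp["age_years"]
        col["age_mean"] = float(ages.mean()) if len(grp) else np.nan
        col["age_sd"] = float(ages.std(ddof=1)) if len(grp) > 1 else np.nan
        col["age_min"] = float(ages.min()) if len(grp) else np.nan
        col["age_max"] = float(ages.max()) if len(grp) else np.nan
        denom = max(len(grp), 1)
        for sex in ("M", "F"):
            cnt = int((grp["sex"] == sex).sum())
            col[f"sex_{sex}_n"] = cnt
            col[f"sex_{sex}_pct"] = round(100.0 * cnt / denom, 1)
        with_tissue = manifest.loc[manifest["person_id"].isin(grp.index)]
        for tissue in tissues_present:
            cnt = int(with_tissue.loc[with_tissue["tissue"] == tissue, "person_id"].nunique())
            col[f"tissue_{tissue}_n"] = cnt
            col[f"tissue_{tissue}_pct"] = round(100.0 * cnt / denom, 1)
        out[label] = col
    return pd.DataFrame(out)
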