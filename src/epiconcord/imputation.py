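"""Golden-standard imputation of missing clock CpGs.

Published clocks use probes that are not all present on newer arrays.
Missing clock probes are filled from a "golden standard" table of mean
beta values stratified by tissue and age group (child < 18 y, adult
>= 18 y), with a deterministic fallback chain: (tissue, age-group)
stratum mean -> tissue mean over strata -> global mean over the table.
Measured values are never overwritten, and the imputed fraction is
capped (published clocks needed at most ~18% imputation).

PC clocks skip this module entirely: their scoring substitutes the
definition's center value for missing probes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .containers import BetaMatrix

AGE_GROUPS = ("child", "adult")


class ImputationError(ValueError):
    pass


@dataclass
class GoldenStandard:
    """Probe x (tissue, age_group) mean-beta reference table.

    ``table`` has a two-level column MultiIndex (tissue, age_group);
    ``n_per_stratum`` records how many samples went into each column.
    """

    table: pd.DataFrame
    n_per_stratum: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = self.table.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            bad = np.nansum((arr < 0) | (arr > 1))
        if bad:
            raise ImputationError(f"{int(bad)} golden means outside [0, 1]")
        for _, age_group in self.table.columns:
            if age_group not in AGE_GROUPS:
                raise ImputationError(f"unknown age group {age_group!r}")

    def strata(self) -> list[tuple[str, str]]:
        return list(self.table.columns)

    # serialization (TSV with tissue.age_group column headers)
    def to_tsv(self, path) -> None:
        flat = self.table.copy()
        flat.columns = [f"{t}.{g}" for t, g in flat.columns]
        flat.rename_axis("probe_id").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "GoldenStandard":
        flat = pd.read_csv(path, sep="\t", index_col="probe_id")
        cols = pd.MultiIndex.from_tuples(
            [tuple(c.rsplit(".", 1)) for c in flat.columns],
            names=["tissue", "age_group"],
        )
        flat.columns = cols
        return cls(table=flat)


def age_group_of(age_years: float, age_cut: float = 18.0) -> str:
    return "child" if age_years < age_cut else "adult"


def build_golden_standard(
    betas: Mapping[str, BetaMatrix | pd.DataFrame],
    manifest: pd.DataFrame,
    age_cut: float = 18.0,
) -> GoldenStandard:
    """Arithmetic per-probe mean beta for each (tissue, age-group) stratum.

    Strata with no samples are omitted with a warning; probes missing
    in all samples of a stratum are absent (NaN) for that stratum.
    """
    meta = manifest.set_index("sample_id")
    columns = {}
    n_per = {}
    for tissue, beta in betas.items():
        values = beta.values if isinstance(beta, BetaMatrix) else beta
        sample_ages = meta.loc[meta.index.intersection(values.columns), "age_years"]
        for group in AGE_GROUPS:
            in_group = sample_ages.index[
                sample_ages.map(lambda a: age_group_of(a, age_cut)) == group
            ]
            if len(in_group) == 0:
                warnings.warn(
                    f"golden standard: empty stratum ({tissue}, {group}); omitted",
                    stacklevel=2,
                )
                continue
            columns[(tissue, group)] = values[in_group].mean(axis=1, skipna=True)
            n_per[(tissue, group)] = int(len(in_group))
    if not columns:
        raise ImputationError("no non-empty strata")
    table = pd.DataFrame(columns)
    table.columns = pd.MultiIndex.from_tuples(
        table.columns, names=["tissue", "age_group"]
    )
    return GoldenStandard(table=table, n_per_stratum=n_per)


def impute_missing(
    beta_vector: pd.Series,
    required_probes: Iterable[str],
    golden: GoldenStandard,
    tissue: str,
    age_group: str,
    max_fraction: float = 0.20,
) -> tuple[pd.Series, pd.DataFrame]:
    """Fill required probes absent (or NaN) in a measured sample.

    Returns ``(completed vector over required_probes, report)``; the
    report lists each imputed probe with its fill source
    (stratum/tissue/global) and the overall imputed fraction.
    Measured values are never overwritten.
    """
    if age_group not in AGE_GROUPS:
        raise ImputationError(f"unknown age group {age_group!r}")
    required = pd.Index(required_probes)
    completed = beta_vector.reindex(required)
    missing = required[completed.isna()]

    frac = len(missing) / max(len(required), 1)
    if frac > max_fraction:
        raise ImputationError(
            f"{len(missing)}/{len(required)} probes missing "
            f"({frac:.1%} > {max_fraction:.0%} cap)"
        )

    table = golden.table
    stratum_col = (
        table[(tissue, age_group)]
        if (tissue, age_group) in table.columns
        else pd.Series(dtype=float)
    )
    tissue_cols = table[tissue] if tissue in table.columns.get_level_values(0) else None
    tissue_mean = (
        tissue_cols.mean(axis=1, skipna=True) if tissue_cols is not None else None
    )
    global_mean = table.mean(axis=1, skipna=True)

    rows = []
    unresolvable = []
    for probe in missing:
        value, source = np.nan, None
        if probe in stratum_col.index and not np.isnan(stratum_col.get(probe, np.nan)):
            value, source = float(stratum_col[probe]), "stratum"
        elif tissue_mean is not None and probe in tissue_mean.index and not np.isnan(
            tissue_mean.get(probe, np.nan)
        ):
            value, source = float(tissue_mean[probe]), "tissue"
        elif probe in global_mean.index and not np.isnan(global_mean.get(probe, np.nan)):
            value, source = float(global_mean[probe]), "global"
        else:
            unresolvable.append(probe)
            continue
        completed[probe] = value
        rows.append({"probe_id": probe, "source": source, "value": value})
    if unresolvable:
        raise ImputationError(
            f"probes absent from measurement and golden table: "
            f"{unresolvable[:10]}"
            + (f" (+{len(unresolvable) - 10} more)" if len(unresolvable) > 10 else "")
        )
    report = pd.DataFrame(rows, columns=["probe_id", "source", "value"])
    report.attrs["imputed_fraction"] = frac
    report.attrs["tissue"] = tissue
    report.attrs["age_group"] = age_group
    return completed, report
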