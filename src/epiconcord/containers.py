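"""Core data containers for methylation-array analysis.

A :class:`BetaMatrix` holds probes x samples methylation fractions (beta
values) together with the aligned per-entry detection p-values and bead
counts, plus the Infinium design type (I/II) of each probe.  Sample-level
metadata lives in a *manifest* table, a plain :class:`pandas.DataFrame`
with a fixed schema validated by :func:`validate_manifest`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

TISSUES = ("buccal", "saliva", "dbs", "buffy_coat", "pbmc")
COHORTS = ("child", "adult")
ORAL_TISSUES = ("buccal", "saliva")
BLOOD_TISSUES = ("dbs", "buffy_coat", "pbmc")

MANIFEST_COLUMNS = (
    "sample_id",
    "person_id",
    "tissue",
    "age_years",
    "sex",
    "cohort",
    "plate",
    "bisulfite_rate",
)


class ValidationError(ValueError):
    """Raised when a container violates its structural invariants."""


@dataclass
class BetaMatrix:
    """Probes x samples beta values with aligned QC layers.

    Parameters
    ----------
    values
        DataFrame of methylation fractions in [0, 1] (NaN allowed),
        indexed by probe id with sample ids as columns.
    detection_p
        Per-entry detection p-values, same shape as ``values``.
    bead_count
        Per-entry bead counts (non-negative integers), same shape.
    probe_type
        Series mapping probe id -> {"I", "II"}.
    meta
        Free-form provenance flags (e.g. ``{"normalized": True}``).
    """

    values: pd.DataFrame
    detection_p: pd.DataFrame | None = None
    bead_count: pd.DataFrame | None = None
    probe_type: pd.Series | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ---------------------------------------------------
    def validate(self) -> None:
        v = self.values
        if not v.index.is_unique:
            raise ValidationError("probe ids are not unique")
        if not v.columns.is_unique:
            raise ValidationError("sample ids are not unique")
        arr = v.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            bad = np.nansum((arr < 0) | (arr > 1))
        if bad:
            raise ValidationError(f"{int(bad)} beta values outside [0, 1]")
        for name in ("detection_p", "bead_count"):
            layer = getattr(self, name)
            if layer is None:
                continue
            if layer.shape != v.shape:
                raise ValidationError(f"{name} shape {layer.shape} != values {v.shape}")
            if not layer.index.equals(v.index) or not layer.columns.equals(v.columns):
                raise ValidationError(f"{name} axes not aligned with values")
        if self.probe_type is not None:
            missing = v.index.difference(self.probe_type.index)
            if len(missing):
                raise ValidationError(f"probe_type missing for {len(missing)} probes")

    # -- accessors ----------------------------------------------------
    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset(
        self,
        probes: Sequence[str] | pd.Index | None = None,
        samples: Sequence[str] | pd.Index | None = None,
    ) -> "BetaMatrix":
        """Return a new BetaMatrix restricted to the given probes/samples."""
        probes = self.probe_ids if probes is None else pd.Index(probes)
        samples = self.sample_ids if samples is None else pd.Index(samples)

        def _cut(df: pd.DataFrame | None) -> pd.DataFrame | None:
            return None if df is None else df.loc[probes, samples]

        ptype = None if self.probe_type is None else self.probe_type.loc[probes]
        return BetaMatrix(
            values=self.values.loc[probes, samples],
            detection_p=_cut(self.detection_p),
            bead_count=_cut(self.bead_count),
            probe_type=ptype,
            meta=dict(self.meta),
        )

    # -- I/O -----------------------------------------------------------
    def to_dir(self, path: str | Path, fmt: str = "tsv") -> None:
        """Write all layers under ``path`` (``values.tsv`` etc.)."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        layers = {
            "values": self.values,
            "detection_p": self.detection_p,
            "bead_count": self.bead_count,
        }
        for name, df in layers.items():
            if df is None:
                continue
            if fmt == "tsv":
                write_matrix_tsv(df, path / f"{name}.tsv")
            elif fmt == "parquet":
                df.to_parquet(path / f"{name}.parquet")
            else:
                raise ValueError(f"unknown format {fmt!r}")
        if self.probe_type is not None:
            pt = self.probe_type.rename("probe_type").rename_axis("probe_id")
            pt.to_frame().to_csv(path / "probe_type.tsv", sep="\t")
        (path / "meta.json").write_text(json.dumps(self.meta, sort_keys=True))

    @classmethod
    def from_dir(cls, path: str | Path) -> "BetaMatrix":
        path = Path(path)

        def _read(name: str) -> pd.DataFrame | None:
            tsv, pq = path / f"{name}.tsv", path / f"{name}.parquet"
            if tsv.exists():
                return read_matrix_tsv(tsv)
            if pq.exists():
                return pd.read_parquet(pq)
            return None

        values = _read("values")
        if values is None:
            raise FileNotFoundError(f"no values.tsv/values.parquet under {path}")
        ptype = None
        if (path / "probe_type.tsv").exists():
            ptype = pd.read_csv(path / "probe_type.tsv", sep="\t", index_col=0)[
                "probe_type"
            ]
        meta = {}
        if (path / "meta.json").exists():
            meta = json.loads((path / "meta.json").read_text())
        return cls(
            values=values,
            detection_p=_read("detection_p"),
            bead_count=_read("bead_count"),
            probe_type=ptype,
            meta=meta,
        )


def write_matrix_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a probes x samples matrix with ``probe_id`` as first column."""
    df.rename_axis("probe_id").to_csv(path, sep="\t")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="probe_id")


def validate_manifest(
    manifest: pd.DataFrame, beta: BetaMatrix | None = None
) -> pd.DataFrame:
    """Check the fixed sample-manifest schema; return the manifest.

    Required columns: sample_id, person_id, tissue, age_years, sex,
    cohort, plate, bisulfite_rate.  Every BetaMatrix sample (if given)
    must be present in the manifest.
    """
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValidationError(f"manifest missing columns: {missing}")
    if manifest["sample_id"].duplicated().any():
        dups = manifest.loc[manifest["sample_id"].duplicated(), "sample_id"]
        raise ValidationError(f"duplicate sample ids: {sorted(set(dups))[:5]}")
    bad_tissue = set(manifest["tissue"]) - set(TISSUES)
    if bad_tissue:
        raise ValidationError(f"unknown tissues: {sorted(bad_tissue)}")
    bad_cohort = set(manifest["cohort"]) - set(COHORTS)
    if bad_cohort:
        raise ValidationError(f"unknown cohorts: {sorted(bad_cohort)}")
    if (manifest["age_years"] <= 0).any():
        raise ValidationError("age_years must be positive")
    if beta is not None:
        absent = set(beta.sample_ids) - set(manifest["sample_id"])
        if absent:
            raise ValidationError(
                f"{len(absent)} matrix samples absent from manifest: "
                f"{sorted(absent)[:5]}"
            )
    return manifest


def write_manifest_tsv(manifest: pd.DataFrame, path: str | Path) -> None:
    manifest.loc[:, list(MANIFEST_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_manifest_tsv(path: str | Path) -> pd.DataFrame:
    return validate_manifest(pd.read_csv(path, sep="\t"))


@dataclass
class CellComposition:
    """Per-sample cell-type (or latent component) proportions.

    ``proportions`` is samples x cell-types; rows are non-negative and
    sum to 1.  ``method`` records whether the estimate came from a
    reference panel or a reference-free factorization.
    """

    proportions: pd.DataFrame
    method: str  # "reference" | "reference-free"
    k: int

    def __post_init__(self) -> None:
        arr = self.proportions.to_numpy(dtype=float)
        if (arr < -1e-9).any():
            raise ValidationError("negative cell proportions")
        sums = arr.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            off = np.abs(sums - 1).max()
            raise ValidationError(f"proportion rows off the simplex by {off:.2e}")
        if self.k != self.proportions.shape[1]:
            raise ValidationError("k does not match number of proportion columns")


def concat_compositions(parts: Iterable[CellComposition]) -> pd.DataFrame:
    """Stack compositions into a tidy table (sample_id, cell_type, proportion, method)."""
    rows = []
    for part in parts:
        long = part.proportions.rename_axis("sample_id").reset_index().melt(
            id_vars="sample_id", var_name="cell_type", value_name="proportion"
        )
        long["method"] = part.method
        rows.append(long)
    return pd.concat(rows, ignore_index=True)
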