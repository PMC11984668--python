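"""Declarative epigenetic-clock definitions and scoring.

A clock is a declarative object: probe weights plus an intercept and an
output transform.  Three kinds are supported:

``linear``
    score = intercept + sum_i w_i * beta_i.
``pc``
    score = intercept + sum_c w_c * sum_i rot_ic * (beta_i - center_i);
    missing probes are substituted by their center value, which makes
    these clocks robust to probe dropout (no imputation needed).
``composite``
    two-stage clocks: sub-scores (each linear in betas, optionally with
    age/sex covariates) feed a combination layer, mirroring the
    surrogate-biomarker construction of GrimAge-style clocks.

Transforms map the raw score to the reported estimate: ``identity``
(years), ``horvath_age`` (the log-linear age calibration used by the
pan-tissue clock family) or ``rate`` (a unitless pace of aging, for
which age acceleration is undefined).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import BetaMatrix

KINDS = ("linear", "composite", "pc")
TRANSFORMS = ("identity", "horvath_age", "rate")


class ClockError(ValueError):
    pass


@dataclass
class SubScore:
    """One surrogate sub-model of a composite clock."""

    name: str
    weights: pd.Series
    intercept: float = 0.0
    covariates: tuple[str, ...] = ()  # subset of ("age", "sex")
    covariate_weights: dict = field(default_factory=dict)


@dataclass
class ClockDefinition:
    name: str
    kind: str  # linear | composite | pc
    intercept: float = 0.0
    weights: pd.Series | None = None  # linear
    transform: str = "identity"
    adult_age: float = 20.0
    # pc clocks
    center: pd.Series | None = None
    rotation: pd.DataFrame | None = None  # probe x component
    component_weights: pd.Series | None = None
    # composite clocks
    sub_scores: list[SubScore] = field(default_factory=list)
    combination_weights: pd.Series | None = None  # over sub-score names + covariates
    # optional pace-style reference-mean normalization (off unless set)
    reference_means: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ClockError(f"unknown clock kind {self.kind!r}")
        if self.transform not in TRANSFORMS:
            raise ClockError(f"unknown transform {self.transform!r}")
        if self.adult_age <= 0:
            raise ClockError("adult_age must be positive")
        if self.kind == "linear" and self.weights is None:
            raise ClockError("linear clock requires weights")
        if self.weights is not None and not self.weights.index.is_unique:
            raise ClockError("duplicate probe ids in weights")
        if self.kind == "pc":
            for part in ("center", "rotation", "component_weights"):
                if getattr(self, part) is None:
                    raise ClockError(f"pc clock requires {part}")
            if not np.isfinite(self.rotation.to_numpy()).all():
                raise ClockError("non-finite rotation loadings")

    # -- probe bookkeeping --------------------------------------------
    @property
    def required_probes(self) -> pd.Index:
        if self.kind == "linear":
            return self.weights.index
        if self.kind == "pc":
            return self.rotation.index
        probes: pd.Index = pd.Index([])
        for sub in self.sub_scores:
            probes = probes.union(sub.weights.index)
        return probes

    @property
    def is_rate(self) -> bool:
        return self.transform == "rate"

    # -- serialization -------------------------------------------------
    def to_dir(self, path: str | Path) -> None:
        """Write JSON metadata + TSV coefficient table(s)."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        meta = {
            "name": self.name,
            "kind": self.kind,
            "intercept": self.intercept,
            "transform": self.transform,
            "adult_age": self.adult_age,
        }
        if self.kind == "linear":
            tbl = self.weights.rename("weight").rename_axis("probe_id").to_frame()
            if self.reference_means is not None:
                tbl["reference_mean"] = self.reference_means
            tbl.to_csv(path / "coefficients.tsv", sep="\t")
        elif self.kind == "pc":
            tbl = self.center.rename("center").rename_axis("probe_id").to_frame()
            tbl.to_csv(path / "coefficients.tsv", sep="\t")
            self.rotation.rename_axis("probe_id").to_csv(path / "loadings.tsv", sep="\t")
            meta["component_weights"] = {
                str(k): float(v) for k, v in self.component_weights.items()
            }
        else:  # composite
            meta["sub_scores"] = [
                {
                    "name": s.name,
                    "intercept": s.intercept,
                    "covariates": list(s.covariates),
                    "covariate_weights": s.covariate_weights,
                }
                for s in self.sub_scores
            ]
            meta["combination_weights"] = {
                str(k): float(v) for k, v in self.combination_weights.items()
            }
            rows = []
            for s in self.sub_scores:
                part = s.weights.rename("weight").rename_axis("probe_id").reset_index()
                part.insert(0, "sub_score", s.name)
                rows.append(part)
            pd.concat(rows, ignore_index=True).to_csv(
                path / "coefficients.tsv", sep="\t", index=False
            )
        (path / "clock.json").write_text(json.dumps(meta, indent=1, sort_keys=True))

    @classmethod
    def from_dir(cls, path: str | Path) -> "ClockDefinition":
        path = Path(path)
        meta = json.loads((path / "clock.json").read_text())
        kind = meta["kind"]
        kwargs = dict(
            name=meta["name"],
            kind=kind,
            intercept=float(meta["intercept"]),
            transform=meta["transform"],
            adult_age=float(meta.get("adult_age", 20.0)),
        )
        coef = pd.read_csv(path / "coefficients.tsv", sep="\t")
        if kind == "linear":
            coef = coef.set_index("probe_id")
            kwargs["weights"] = coef["weight"]
            if "reference_mean" in coef.columns:
                kwargs["reference_means"] = coef["reference_mean"]
        elif kind == "pc":
            kwargs["center"] = coef.set_index("probe_id")["center"]
            kwargs["rotation"] = pd.read_csv(
                path / "loadings.tsv", sep="\t", index_col="probe_id"
            )
            kwargs["component_weights"] = pd.Series(meta["component_weights"])
        else:
            subs = []
            for entry in meta["sub_scores"]:
                w = coef.loc[coef["sub_score"] == entry["name"]].set_index("probe_id")[
                    "weight"
                ]
                subs.append(
                    SubScore(
                        name=entry["name"],
                        weights=w,
                        intercept=float(entry["intercept"]),
                        covariates=tuple(entry["covariates"]),
                        covariate_weights=dict(entry["covariate_weights"]),
                    )
                )
            kwargs["sub_scores"] = subs
            kwargs["combination_weights"] = pd.Series(meta["combination_weights"])
        return cls(**kwargs)


# -- age calibration ---------------------------------------------------


def horvath_age_transform(age: float, adult_age: float = 20.0) -> float:
    """Forward calibration: chronological age -> clock training scale.

    Logarithmic below ``adult_age`` (fast epigenetic drift in
    development), linear above.
    """
    if age <= adult_age:
        return math.log((age + 1.0) / (adult_age + 1.0))
    return (age - adult_age) / (adult_age + 1.0)


def horvath_anti_transform(score: float, adult_age: float = 20.0) -> float:
    """Inverse calibration: raw clock score -> age in years."""
    if not np.isfinite(score):
        raise ClockError("non-finite clock score")
    if score <= 0:
        return (adult_age + 1.0) * math.exp(score) - 1.0
    return (adult_age + 1.0) * score + adult_age


# -- scoring -----------------------------------------------------------


def apply_clock(
    clock: ClockDefinition,
    beta_vector: pd.Series,
    covariates: Mapping[str, float] | None = None,
) -> float:
    """Compute the raw (pre-transform) score of one sample.

    Linear and composite clocks require every clock probe to be present
    and non-missing (impute first); pc clocks substitute the center
    value for missing probes.
    """
    if clock.kind == "linear":
        beta = beta_vector.reindex(clock.weights.index)
        if clock.reference_means is not None:
            beta = beta - clock.reference_means.reindex(clock.weights.index)
        missing = beta.index[beta.isna()]
        if len(missing):
            raise ClockError(
                f"clock {clock.name!r}: {len(missing)} probes missing, "
                f"e.g. {list(missing[:5])}"
            )
        return float(clock.intercept + beta.to_numpy() @ clock.weights.to_numpy())
    if clock.kind == "pc":
        beta = beta_vector.reindex(clock.rotation.index)
        centered = (beta - clock.center.reindex(clock.rotation.index)).fillna(0.0)
        scores = centered.to_numpy() @ clock.rotation.to_numpy()
        w = clock.component_weights.reindex(clock.rotation.columns).to_numpy()
        return float(clock.intercept + scores @ w)
    # composite
    covariates = dict(covariates or {})
    parts: dict[str, float] = {}
    for sub in clock.sub_scores:
        beta = beta_vector.reindex(sub.weights.index)
        missing = beta.index[beta.isna()]
        if len(missing):
            raise ClockError(
                f"sub-score {sub.name!r}: {len(missing)} probes missing"
            )
        val = sub.intercept + float(beta.to_numpy() @ sub.weights.to_numpy())
        for cov in sub.covariates:
            if cov not in covariates:
                raise ClockError(
                    f"sub-score {sub.name!r} requires covariate {cov!r}"
                )
            val += sub.covariate_weights.get(cov, 0.0) * float(covariates[cov])
        parts[sub.name] = val
    total = clock.intercept
    for key, w in clock.combination_weights.items():
        if key in parts:
            total += w * parts[key]
        elif key in covariates:
            total += w * float(covariates[key])
        else:
            raise ClockError(f"combination term {key!r} has no sub-score/covariate")
    return float(total)


def transform_score(clock: ClockDefinition, score: float) -> float:
    """Raw score -> reported estimate (years, or unitless pace)."""
    if clock.transform == "horvath_age":
        return horvath_anti_transform(score, clock.adult_age)
    return score  # identity and rate report the raw score


def compute_estimates(
    clocks: Sequence[ClockDefinition],
    beta: BetaMatrix | pd.DataFrame,
    manifest: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Score every sample with every clock.

    Returns a tidy frame: sample_id, clock, raw_score, estimate,
    transform.  Covariates (age, sex) for composite clocks are pulled
    from the manifest when provided.
    """
    values = beta.values if isinstance(beta, BetaMatrix) else beta
    cov_by_sample: dict[str, dict[str, float]] = {}
    if manifest is not None:
        for _, row in manifest.iterrows():
            cov_by_sample[row["sample_id"]] = {
                "age": float(row["age_years"]),
                "sex": 1.0 if str(row["sex"]).upper().startswith("F") else 0.0,
            }
    rows = []
    for clock in clocks:
        for sample in values.columns:
            raw = apply_clock(
                clock, values[sample], covariates=cov_by_sample.get(sample)
            )
            rows.append(
                {
                    "sample_id": sample,
                    "clock": clock.name,
                    "raw_score": raw,
                    "estimate": transform_score(clock, raw),
                    "transform": clock.transform,
                }
            )
    return pd.DataFrame(rows)


def compute_acceleration(
    estimates: pd.DataFrame, manifest: pd.DataFrame
) -> pd.DataFrame:
    """Add age acceleration: estimate − chronological age, in years.

    Rate (pace-style) clocks have no acceleration; their rows keep NaN.
    Requesting acceleration for a rate clock explicitly is an error via
    :func:`acceleration_for`.
    """
    ages = manifest.set_index("sample_id")["age_years"]
    missing = set(estimates["sample_id"]) - set(ages.index)
    if missing:
        raise ClockError(f"no chronological age for samples: {sorted(missing)[:5]}")
    out = estimates.copy()
    accel = out["estimate"] - out["sample_id"].map(ages)
    accel[out["transform"] == "rate"] = np.nan
    out["acceleration"] = accel
    return out


def acceleration_for(estimates: pd.DataFrame, clock_name: str) -> pd.Series:
    """Per-sample acceleration of one clock; refuses rate clocks."""
    sub = estimates.loc[estimates["clock"] == clock_name]
    if sub.empty:
        raise ClockError(f"no estimates for clock {clock_name!r}")
    if (sub["transform"] == "rate").any():
        raise ClockError(
            f"clock {clock_name!r} is a pace-of-aging (rate) clock; "
            "age acceleration is undefined for it"
        )
    return sub.set_index("sample_id")["acceleration"]
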