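"""Synthetic multi-tissue methylation cohorts with known ground truth.

The generator emulates the design of a two-cohort, five-tissue
within-person study: children (~9-14 y, buccal / saliva / dried blood
spot / buffy coat) and adults (~19-70 y, buccal / saliva / DBS / PBMC).
Every sample is a Dirichlet mixture of tissue-specific cell-type
methylomes, with

* an age effect on a designated probe subset, linear on the beta scale
  in the log-linearly calibrated age (so that a linear clock inverts it
  exactly in the noiseless case),
* a plate (batch) effect on the logit scale, shared by all samples of a
  person and visible in a dedicated control-probe matrix,
* heteroscedastic measurement noise added on the logit scale, and
* optional Infinium type II compression toward 0.5, probe dropout and
  injected QC failures (detection-p inflation / low bisulfite
  conversion).

All randomness flows from a single :class:`numpy.random.Generator`
seeded by ``SimConfig.seed``; identical configs produce bit-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .clocks import ClockDefinition, horvath_age_transform
from .containers import BetaMatrix, validate_manifest

_EPS = 1e-6

DEFAULT_TISSUES_CHILDREN = ("buccal", "saliva", "dbs", "buffy_coat")
DEFAULT_TISSUES_ADULTS = ("buccal", "saliva", "dbs", "pbmc")

# Per-tissue number of cell types: oral tissues get the data-driven K
# reported for reference-free decomposition (buccal 3, saliva 5); blood
# tissues get their immune panels.
DEFAULT_K = {"buccal": 3, "saliva": 5, "dbs": 6, "buffy_coat": 6, "pbmc": 5}

CELL_NAMES = {
    "buccal": ["epithelial", "immune", "fibroblast"],
    "saliva": ["epithelial", "neutrophil", "lymphocyte", "monocyte", "other"],
    "dbs": ["CD4T", "CD8T", "NK", "B", "monocyte", "granulocyte"],
    "buffy_coat": ["CD4T", "CD8T", "NK", "B", "monocyte", "granulocyte"],
    "pbmc": ["CD4T", "CD8T", "NK", "B", "monocyte"],
}


class SimConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Ranges/sizes default to the study design being emulated (36
    children aged ~9-14, 47 adults aged ~19-70, four tissues per
    cohort); noise scales are logit-scale standard deviations.
    """

    n_children: int = 36
    n_adults: int = 47
    child_age_range: tuple[float, float] = (9.4, 13.94)
    adult_age_range: tuple[float, float] = (19.2, 70.21)
    tissues_children: tuple[str, ...] = DEFAULT_TISSUES_CHILDREN
    tissues_adults: tuple[str, ...] = DEFAULT_TISSUES_ADULTS
    n_probes: int = 2000
    n_age_probes: int = 200
    n_cell_types: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_K))
    dirichlet_concentration: Mapping[str, float] | float = 3.0
    noise_sd: float = 0.05
    # "logit" (default): heteroscedastic array-like noise; "beta":
    # additive noise on the beta scale, preserving the exact low-rank
    # mean structure of the cell mixtures
    noise_scale: str = "logit"
    n_batches: int = 2
    batch_sd: float = 0.15
    batch_probe_fraction: float = 0.2
    n_control_probes: int = 100
    missing_probe_fraction: float = 0.0
    qc_fail_fraction: float = 0.0
    probe_fail_fraction: float = 0.0
    type2_fraction: float = 0.8
    type2_compression: float = 1.0  # 1.0 = no compression
    adult_age: float = 20.0  # knot of the age calibration
    # optional explicit design: cohort -> tissue -> number of persons sampled
    samples_per_tissue: Mapping[str, Mapping[str, int]] | None = None
    # optional explicit injected QC failures: tissue -> count
    qc_fail_samples: Mapping[str, int] | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_children < 0 or self.n_adults < 0:
            raise SimConfigError("person counts must be >= 0")
        if self.n_children + self.n_adults == 0:
            raise SimConfigError("zero persons")
        for lo, hi in (self.child_age_range, self.adult_age_range):
            if lo > hi:
                raise SimConfigError("age range not ordered")
        for frac in (
            self.missing_probe_fraction,
            self.qc_fail_fraction,
            self.probe_fail_fraction,
            self.type2_fraction,
        ):
            if not 0.0 <= frac <= 1.0:
                raise SimConfigError("fractions must lie in [0, 1]")
        if self.n_age_probes > self.n_probes:
            raise SimConfigError("n_age_probes exceeds n_probes")
        for tissue in set(self.tissues_children) | set(self.tissues_adults):
            k = self.n_cell_types.get(tissue)
            if k is None:
                raise SimConfigError(f"tissue {tissue!r} has no cell-type count")
            if k < 1:
                raise SimConfigError(f"tissue {tissue!r} needs K >= 1")
        if self.n_batches < 1:
            raise SimConfigError("need at least one batch")
        if self.noise_sd < 0 or self.batch_sd < 0:
            raise SimConfigError("noise scales must be non-negative")
        if self.noise_scale not in ("logit", "beta"):
            raise SimConfigError(f"unknown noise_scale {self.noise_scale!r}")


@dataclass
class SimTruth:
    """Ground truth of a generated cohort."""

    true_age: pd.Series  # person -> years
    true_proportions: dict  # tissue -> DataFrame (sample x cell type)
    true_k: dict  # tissue -> K
    batch_of: pd.Series  # sample -> batch id
    age_probe_ids: pd.Index
    cell_reference: dict  # tissue -> DataFrame (probe x cell type)
    age_baseline: pd.Series  # age probe -> baseline beta m_j
    age_slope: pd.Series  # age probe -> slope s_j (per calibrated-age unit)
    batch_probes: pd.Index
    adult_age: float = 20.0

    def validate(self) -> None:
        for tissue, props in self.true_proportions.items():
            sums = props.to_numpy().sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-12):
                raise SimConfigError(f"{tissue}: proportions off the simplex")


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p) - np.log1p(-p)


def _inv_logit(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _cell_names(tissue: str, k: int) -> list[str]:
    names = CELL_NAMES.get(tissue, [])
    if len(names) == k:
        return list(names)
    return [f"{tissue}_ct{i + 1}" for i in range(k)]


def generate_cohort(
    config: SimConfig,
) -> tuple[dict[str, BetaMatrix], pd.DataFrame, pd.DataFrame, SimTruth]:
    """Simulate one cohort.

    Returns ``(betas, manifest, controls, truth)`` where ``betas`` maps
    tissue -> :class:`BetaMatrix`, ``manifest`` is the sample manifest,
    ``controls`` the control-probe beta matrix (probe x sample) and
    ``truth`` the generative ground truth.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    # ---- persons ----------------------------------------------------
    person_rows = []
    for i in range(config.n_children):
        person_rows.append((f"C{i + 1:03d}", "child"))
    for i in range(config.n_adults):
        person_rows.append((f"A{i + 1:03d}", "adult"))
    person_ids = [p for p, _ in person_rows]
    cohorts = {p: c for p, c in person_rows}
    ages = {}
    for pid, coh in person_rows:
        lo, hi = (
            config.child_age_range if coh == "child" else config.adult_age_range
        )
        ages[pid] = float(rng.uniform(lo, hi))
    sexes = {p: ("F" if rng.random() < 0.5 else "M") for p in person_ids}
    plate_idx = rng.permuted(np.arange(len(person_ids)) % config.n_batches)
    plates = {p: f"plate{plate_idx[i] + 1}" for i, p in enumerate(person_ids)}

    # ---- probe universe ---------------------------------------------
    probe_ids = pd.Index([f"cg{i:06d}" for i in range(config.n_probes)])
    probe_type = pd.Series(
        np.where(rng.random(config.n_probes) < config.type2_fraction, "II", "I"),
        index=probe_ids,
        name="probe_type",
    )
    age_pos = np.sort(
        rng.choice(config.n_probes, size=config.n_age_probes, replace=False)
    )
    age_probe_ids = probe_ids[age_pos]
    m = rng.uniform(0.40, 0.55, size=config.n_age_probes)
    s = rng.uniform(0.05, 0.15, size=config.n_age_probes) * rng.choice(
        [-1.0, 1.0], size=config.n_age_probes
    )
    age_baseline = pd.Series(m, index=age_probe_ids)
    age_slope = pd.Series(s, index=age_probe_ids)

    # ---- cell references (age probes are cell-type invariant) -------
    tissues = sorted(set(config.tissues_children) | set(config.tissues_adults))
    cell_reference: dict[str, pd.DataFrame] = {}
    for tissue in tissues:
        k = int(config.n_cell_types[tissue])
        # U-shaped baseline: most CpGs sit near fully un/methylated,
        # as on real arrays; markers and age probes fill the middle
        base = 0.02 + 0.96 * rng.beta(0.45, 0.45, size=config.n_probes)
        ref = np.tile(base[:, None], (1, k))
        # ~30% of probes discriminate cell types: a random subset of
        # types is pushed high, the rest low.
        marker = rng.random(config.n_probes) < 0.3
        for j in np.where(marker)[0]:
            hi = rng.random(k) < 0.5
            if hi.all() or (~hi).all():
                hi[int(rng.integers(k))] = not hi[int(rng.integers(k))]
            ref[j, hi] = rng.uniform(0.75, 0.95, size=hi.sum())
            ref[j, ~hi] = rng.uniform(0.05, 0.25, size=(~hi).sum())
        ref[age_pos, :] = m[:, None]
        cell_reference[tissue] = pd.DataFrame(
            ref, index=probe_ids, columns=_cell_names(tissue, k)
        )

    # ---- batch effects ----------------------------------------------
    n_batch_probes = int(round(config.batch_probe_fraction * config.n_probes))
    batch_pos = np.sort(
        rng.choice(config.n_probes, size=n_batch_probes, replace=False)
    )
    batch_probes = probe_ids[batch_pos]
    batch_ids = [f"plate{b + 1}" for b in range(config.n_batches)]
    batch_shift = {
        b: rng.normal(0.0, config.batch_sd, size=n_batch_probes)
        if config.batch_sd > 0
        else np.zeros(n_batch_probes)
        for b in batch_ids
    }
    control_ids = pd.Index([f"ctrl{i:04d}" for i in range(config.n_control_probes)])
    control_base = rng.uniform(0.2, 0.8, size=config.n_control_probes)
    control_shift = {
        b: rng.normal(0.0, config.batch_sd, size=config.n_control_probes)
        if config.batch_sd > 0
        else np.zeros(config.n_control_probes)
        for b in batch_ids
    }

    # ---- which persons contribute which tissues ---------------------
    cohort_tissues = {"child": config.tissues_children, "adult": config.tissues_adults}
    members = {
        "child": [p for p in person_ids if cohorts[p] == "child"],
        "adult": [p for p in person_ids if cohorts[p] == "adult"],
    }
    design: list[tuple[str, str]] = []  # (person, tissue)
    for coh in ("child", "adult"):
        for tissue in cohort_tissues[coh]:
            pool = members[coh]
            if not pool:
                continue
            count = len(pool)
            if config.samples_per_tissue is not None:
                count = int(
                    config.samples_per_tissue.get(coh, {}).get(tissue, len(pool))
                )
            if count > len(pool):
                raise SimConfigError(
                    f"{coh}/{tissue}: requested {count} persons, have {len(pool)}"
                )
            chosen = (
                pool
                if count == len(pool)
                else sorted(rng.choice(pool, size=count, replace=False))
            )
            design.extend((p, tissue) for p in chosen)

    # ---- injected QC failures ---------------------------------------
    sample_ids = [f"{p}_{t}" for p, t in design]
    fail_set: dict[str, str] = {}  # sample -> mode
    if config.qc_fail_samples:
        for tissue, count in config.qc_fail_samples.items():
            candidates = [sid for sid, (p, t) in zip(sample_ids, design) if t == tissue]
            if count > len(candidates):
                raise SimConfigError(f"cannot fail {count} {tissue} samples")
            chosen = sorted(rng.choice(candidates, size=count, replace=False))
            for i, sid in enumerate(chosen):
                fail_set[sid] = "detection" if i % 2 == 0 else "bisulfite"
    if config.qc_fail_fraction > 0:
        n_fail = int(round(config.qc_fail_fraction * len(sample_ids)))
        pool = [sid for sid in sample_ids if sid not in fail_set]
        chosen = sorted(rng.choice(pool, size=min(n_fail, len(pool)), replace=False))
        for i, sid in enumerate(chosen):
            fail_set[sid] = "detection" if i % 2 == 0 else "bisulfite"

    # ---- per-tissue matrices ----------------------------------------
    type2_mask = (probe_type == "II").to_numpy()
    betas: dict[str, BetaMatrix] = {}
    manifest_rows = []
    true_props: dict[str, pd.DataFrame] = {}
    control_cols: dict[str, np.ndarray] = {}

    for tissue in tissues:
        t_pairs = [(p, t) for p, t in design if t == tissue]
        if not t_pairs:
            continue
        k = int(config.n_cell_types[tissue])
        names = _cell_names(tissue, k)
        conc = config.dirichlet_concentration
        alpha = (
            np.full(k, float(conc))
            if np.isscalar(conc)
            else np.full(k, float(conc[tissue]))
        )
        ref = cell_reference[tissue].to_numpy()
        cols, detp_cols, bead_cols, props = {}, {}, {}, []
        for person, _ in t_pairs:
            sid = f"{person}_{tissue}"
            w = rng.dirichlet(alpha) if k > 1 else np.ones(1)
            props.append(w)
            mix = ref @ w
            t_cal = horvath_age_transform(ages[person], config.adult_age)
            mix[age_pos] = m + s * t_cal
            x = _logit(np.clip(mix, _EPS, 1.0 - _EPS))
            x[batch_pos] += batch_shift[plates[person]]
            if config.noise_sd > 0 and config.noise_scale == "logit":
                x += rng.normal(0.0, config.noise_sd, size=config.n_probes)
            beta_vec = _inv_logit(x)
            if config.noise_sd > 0 and config.noise_scale == "beta":
                beta_vec += rng.normal(0.0, config.noise_sd, size=config.n_probes)
            beta_vec = np.clip(beta_vec, _EPS, 1.0 - _EPS)
            if config.type2_compression != 1.0:
                beta_vec[type2_mask] = 0.5 + config.type2_compression * (
                    beta_vec[type2_mask] - 0.5
                )
            cols[sid] = beta_vec
            detp = rng.uniform(0.0, 0.002, size=config.n_probes)
            bead = rng.poisson(14.0, size=config.n_probes).astype(int) + 1
            bis = float(rng.uniform(0.90, 0.99))
            mode = fail_set.get(sid)
            if mode == "detection":
                n_bad = int(round(0.10 * config.n_probes))
                bad = rng.choice(config.n_probes, size=n_bad, replace=False)
                detp[bad] = rng.uniform(0.06, 0.5, size=n_bad)
            elif mode == "bisulfite":
                bis = float(rng.uniform(0.60, 0.75))
            detp_cols[sid] = detp
            bead_cols[sid] = bead
            manifest_rows.append(
                {
                    "sample_id": sid,
                    "person_id": person,
                    "tissue": tissue,
                    "age_years": ages[person],
                    "sex": sexes[person],
                    "cohort": cohorts[person],
                    "plate": plates[person],
                    "bisulfite_rate": bis,
                }
            )
            # control probes for this sample
            cx = _logit(control_base) + control_shift[plates[person]]
            if config.noise_sd > 0:
                cx = cx + rng.normal(0.0, config.noise_sd, size=config.n_control_probes)
            control_cols[sid] = np.clip(_inv_logit(cx), _EPS, 1.0 - _EPS)

        sids = list(cols)
        values = pd.DataFrame(cols, index=probe_ids)
        detection_p = pd.DataFrame(detp_cols, index=probe_ids)
        bead_count = pd.DataFrame(bead_cols, index=probe_ids)

        # probe-level injected failures (mean det-p above cutoff or low
        # bead counts in enough samples)
        if config.probe_fail_fraction > 0:
            n_bad = int(round(config.probe_fail_fraction * config.n_probes))
            bad_pos = rng.choice(config.n_probes, size=n_bad, replace=False)
            half = n_bad // 2
            detection_p.iloc[bad_pos[:half], :] = rng.uniform(
                0.06, 0.2, size=(half, len(sids))
            )
            n_low = max(1, int(np.ceil(0.05 * len(sids))))
            for j in bad_pos[half:]:
                hit = rng.choice(len(sids), size=n_low, replace=False)
                bead_count.iloc[j, hit] = 2

        # whole-probe dropout per tissue
        keep = probe_ids
        if config.missing_probe_fraction > 0:
            n_drop = int(round(config.missing_probe_fraction * config.n_probes))
            drop_pos = rng.choice(config.n_probes, size=n_drop, replace=False)
            keep = probe_ids.delete(np.sort(drop_pos))
        betas[tissue] = BetaMatrix(
            values=values.loc[keep],
            detection_p=detection_p.loc[keep],
            bead_count=bead_count.loc[keep],
            probe_type=probe_type.loc[keep],
            meta={"tissue": tissue, "normalized": False},
        )
        true_props[tissue] = pd.DataFrame(props, index=sids, columns=names)

    manifest = pd.DataFrame(manifest_rows)
    validate_manifest(manifest)
    controls = pd.DataFrame(
        control_cols, index=control_ids
    ).loc[:, manifest["sample_id"].tolist()]

    truth = SimTruth(
        true_age=pd.Series(ages, name="age_years"),
        true_proportions=true_props,
        true_k={t: int(config.n_cell_types[t]) for t in tissues},
        batch_of=manifest.set_index("sample_id")["plate"],
        age_probe_ids=age_probe_ids,
        cell_reference=cell_reference,
        age_baseline=age_baseline,
        age_slope=age_slope,
        batch_probes=batch_probes,
        adult_age=config.adult_age,
    )
    truth.validate()
    return betas, manifest, controls, truth


def generate_clock_definitions(
    config: SimConfig, truth: SimTruth
) -> list[ClockDefinition]:
    """Clock definitions that invert the generative age map.

    Returns (i) a linear age clock exact on noiseless data, (ii) a
    pace-style rate clock (no acceleration defined) and (iii) a PC
    clock over the age-probe block equivalent to the linear one.
    """
    if len(truth.age_probe_ids) == 0:
        raise SimConfigError("no age probes; cannot build clocks")
    s = truth.age_slope.to_numpy()
    m = truth.age_baseline.to_numpy()
    probes = truth.age_probe_ids

    # least-squares inverse of beta_j = m_j + s_j * t : t = sum w_j (beta_j - m_j)
    w = s / float(s @ s)
    linear = ClockDefinition(
        name="sim_linear_age",
        kind="linear",
        intercept=float(-(w @ m)),
        weights=pd.Series(w, index=probes),
        transform="horvath_age",
        adult_age=truth.adult_age,
    )

    # pace-style clock: score = 1 + 0.05 * t, a unitless rate
    wr = 0.05 * w
    rate = ClockDefinition(
        name="sim_pace",
        kind="linear",
        intercept=float(1.0 - wr @ m),
        weights=pd.Series(wr, index=probes),
        transform="rate",
    )

    # PC clock: first component along the age direction, two orthogonal
    # nuisance components with zero weight
    rng = np.random.default_rng(config.seed + 1)
    v1 = s / np.linalg.norm(s)
    basis = [v1]
    while len(basis) < min(3, len(s)):
        cand = rng.normal(size=len(s))
        for b in basis:
            cand -= (cand @ b) * b
        norm = np.linalg.norm(cand)
        if norm > 1e-8:
            basis.append(cand / norm)
    rotation = pd.DataFrame(
        np.column_stack(basis),
        index=probes,
        columns=[f"PC{i + 1}" for i in range(len(basis))],
    )
    comp_w = pd.Series(0.0, index=rotation.columns)
    comp_w.iloc[0] = 1.0 / np.linalg.norm(s)
    pc = ClockDefinition(
        name="sim_pc_age",
        kind="pc",
        intercept=0.0,
        center=pd.Series(m, index=probes),
        rotation=rotation,
        component_weights=comp_w,
        transform="horvath_age",
        adult_age=truth.adult_age,
    )
    return [linear, rate, pc]


def generate_golden_standard(
    betas: Mapping[str, BetaMatrix],
    manifest: pd.DataFrame,
    truth: SimTruth | None = None,
    age_cut: float = 18.0,
):
    """Tissue- and age-stratified mean-beta reference for imputation.

    Thin wrapper over :func:`epiconcord.imputation.build_golden_standard`
    applied to the generated matrices.
    """
    from .imputation import build_golden_standard

    return build_golden_standard(betas, manifest, age_cut=age_cut)
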