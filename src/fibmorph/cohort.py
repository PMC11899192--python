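"""Synthetic cohorts with configurable age and sex structure.

The simulator draws per-subject morphometry (BT, BA, g, MPI) from a four-cell
group model (sex x age-group) with per-sex linear age effects centered on each
group's age midpoint, plus covariates (BMI, subcutaneous fat thickness, muscle
fat infiltration class). Two modes:

* **table mode** — samples the morphometric quantities directly; fast, used
  for replicate sweeps and null calibration.
* **image mode** — additionally renders a multi-slice annular phantom stack
  per subject whose geometry realizes the sampled BT and g, so the full
  image-based measurement pipeline can be exercised end to end. In this mode
  BA (and CL) are implied by the ring geometry, so the table's ``true_BA`` is
  overwritten by the rendered truth.

Generation is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .errors import CohortTooSmallError, InvalidSpecError
from .phantom import PhantomSpec, compute_truth, make_annulus_phantom
from .types import SubjectStack

__all__ = [
    "GroupParams",
    "CohortSpec",
    "default_cohort_spec",
    "make_cohort",
]

GROUP_NAMES = ("F<=50", "M<=50", "F>50", "M>50")
MFI_CLASSES = ("normal", "mild", "moderate")

# g is truncated to the study population's observed range rather than the
# open (0, 1): below ~0.14 the marrow cavity falls under the 0.7 mm pixel
# size (the ring renders as a filled disk), and the image-mode outer diameter
# D_out = 2 BT / (1 - g) is unbounded as g -> 1.
G_BOUNDS = (0.14, 0.80)


@dataclass
class GroupParams:
    """Sampling parameters for one sex x age-group cell."""

    n: int
    age_range: tuple[float, float]
    bt_mean: float
    bt_sd: float
    ba_mean: float
    ba_sd: float
    g_mean: float
    g_sd: float
    mpi_mean: float
    mpi_sd: float
    mfi_probs: dict[str, float] = field(
        default_factory=lambda: {"normal": 0.4, "mild": 0.4, "moderate": 0.2}
    )

    def validate(self, name: str) -> None:
        if self.n < 0:
            raise InvalidSpecError(f"group {name}: n must be >= 0")
        for sd in (self.bt_sd, self.ba_sd, self.g_sd, self.mpi_sd):
            if sd < 0:
                raise InvalidSpecError(f"group {name}: SDs must be >= 0")
        if self.age_range[0] > self.age_range[1]:
            raise InvalidSpecError(f"group {name}: empty age range")
        total = sum(self.mfi_probs.get(c, 0.0) for c in MFI_CLASSES)
        if abs(total - 1.0) > 1e-9:
            raise InvalidSpecError(
                f"group {name}: MFI class probabilities sum to {total}, not 1"
            )


@dataclass
class CohortSpec:
    """Full specification of a synthetic cohort."""

    groups: dict[str, GroupParams]
    bt_age_slope: dict[str, float] = field(default_factory=lambda: {"F": 0.0, "M": 0.0})
    mpi_age_slope: dict[str, float] = field(default_factory=lambda: {"F": 0.0, "M": 0.0})
    bmi_distribution: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "F": {"mean": 30.3, "sd": 5.7},
            "M": {"mean": 28.4, "sd": 4.4},
        }
    )
    sft_distribution: dict[str, float] = field(
        default_factory=lambda: {"mean": 5.0, "sd": 2.0}
    )
    seed: int = 0
    # image-mode rendering options
    n_slices: int = 9
    slice_jitter: float = 0.02
    deformation_amplitude: float = 0.05
    pixel_spacing: float = 0.7
    supersample_factor: int = 8
    image_noise_sd: float = 0.02

    def validate(self) -> None:
        for name, gp in self.groups.items():
            gp.validate(name)
        if not 0 <= self.slice_jitter <= 0.1:
            raise InvalidSpecError("slice_jitter must be in [0, 0.1]")
        for dist in self.bmi_distribution.values():
            if dist["sd"] < 0:
                raise InvalidSpecError("BMI sd must be >= 0")
        if self.sft_distribution["sd"] < 0:
            raise InvalidSpecError("SFT sd must be >= 0")


def _group_params_from_dict(d: dict) -> GroupParams:
    if "bt_mean" in d:  # flattened (dataclasses.asdict) form round-trips too
        return GroupParams(
            **{**d, "age_range": tuple(d["age_range"]),
               "mfi_probs": dict(d["mfi_probs"])}
        )
    return GroupParams(
        n=int(d["n"]),
        age_range=(float(d["age_range"][0]), float(d["age_range"][1])),
        bt_mean=float(d["bt"]["mean"]),
        bt_sd=float(d["bt"]["sd"]),
        ba_mean=float(d["ba"]["mean"]),
        ba_sd=float(d["ba"]["sd"]),
        g_mean=float(d["g"]["mean"]),
        g_sd=float(d["g"]["sd"]),
        mpi_mean=float(d["mpi"]["mean"]),
        mpi_sd=float(d["mpi"]["sd"]),
        mfi_probs={k: float(v) for k, v in d["mfi_probs"].items()},
    )


def cohort_spec_from_dict(cfg: dict) -> CohortSpec:
    groups = {name: _group_params_from_dict(d) for name, d in cfg["groups"].items()}
    spec = CohortSpec(
        groups=groups,
        bt_age_slope={k: float(v) for k, v in cfg.get("bt_age_slope", {}).items()},
        mpi_age_slope={k: float(v) for k, v in cfg.get("mpi_age_slope", {}).items()},
        bmi_distribution=cfg.get(
            "bmi_distribution", CohortSpec(groups={}).bmi_distribution
        ),
        sft_distribution=cfg.get("sft_distribution", {"mean": 5.0, "sd": 2.0}),
        seed=int(cfg.get("seed", 0)),
    )
    for key in (
        "n_slices",
        "slice_jitter",
        "deformation_amplitude",
        "pixel_spacing",
        "supersample_factor",
        "image_noise_sd",
    ):
        if key in cfg:
            spec = replace(spec, **{key: cfg[key]})
    return spec


def default_cohort_spec(seed: int | None = None) -> CohortSpec:
    """The packaged study-derived default cohort (107 subjects, 4 groups)."""
    text = (
        importlib.resources.files("fibmorph.data")
        .joinpath("default_cohort.yaml")
        .read_text()
    )
    spec = cohort_spec_from_dict(yaml.safe_load(text))
    if seed is not None:
        spec = replace(spec, seed=int(seed))
    return spec


def _sex_of(group_name: str) -> str:
    return "F" if group_name.startswith("F") else "M"


def _truncate(values: np.ndarray, lo: float, hi: float | None = None) -> np.ndarray:
    return np.clip(values, lo, hi)


def make_cohort(
    spec: CohortSpec,
    mode: str = "table",
) -> tuple[pd.DataFrame, list[SubjectStack] | None]:
    """Generate a synthetic cohort.

    Returns ``(table, stacks)`` where ``table`` has one row per subject with
    columns ``subject_id, sex, age, bmi, mfi_class, sft, true_BT, true_BA,
    true_g, true_MPI`` (image mode adds ``true_CL, true_BMA, true_D_out``),
    and ``stacks`` is a list of rendered :class:`SubjectStack` in image mode,
    else ``None``.
    """
    if mode not in ("table", "image"):
        raise InvalidSpecError(f"mode must be 'table' or 'image', got {mode!r}")
    spec.validate()
    for name, gp in spec.groups.items():
        if 0 < gp.n < 2:
            raise CohortTooSmallError(
                f"group {name} has n={gp.n}; two-group tests need n >= 2 per group"
            )

    rng = np.random.default_rng(spec.seed)
    rows = []
    sid = 0
    for name in sorted(spec.groups):  # fixed order for reproducibility
        gp = spec.groups[name]
        sex = _sex_of(name)
        lo, hi = gp.age_range
        mid = (lo + hi) / 2
        ages = rng.uniform(lo, hi, size=gp.n)
        bt_slope = spec.bt_age_slope.get(sex, 0.0)
        mpi_slope = spec.mpi_age_slope.get(sex, 0.0)
        bt = gp.bt_mean + bt_slope * (ages - mid) + rng.normal(0, gp.bt_sd, gp.n)
        ba = gp.ba_mean + rng.normal(0, gp.ba_sd, gp.n)
        gfac = gp.g_mean + rng.normal(0, gp.g_sd, gp.n)
        mpi = gp.mpi_mean + mpi_slope * (ages - mid) + rng.normal(0, gp.mpi_sd, gp.n)
        bt = _truncate(bt, 0.2)
        ba = _truncate(ba, 1.0)
        gfac = _truncate(gfac, *G_BOUNDS)
        mpi = _truncate(mpi, 0.01, 1.0)
        bmi_d = spec.bmi_distribution[sex]
        bmi = _truncate(rng.normal(bmi_d["mean"], bmi_d["sd"], gp.n), 10.0)
        sft = _truncate(
            rng.normal(
                spec.sft_distribution["mean"], spec.sft_distribution["sd"], gp.n
            ),
            0.1,
        )
        probs = [gp.mfi_probs[c] for c in MFI_CLASSES]
        mfi = rng.choice(MFI_CLASSES, size=gp.n, p=probs)
        for i in range(gp.n):
            rows.append(
                dict(
                    subject_id=f"S{sid:04d}",
                    sex=sex,
                    age=ages[i],
                    bmi=bmi[i],
                    mfi_class=mfi[i],
                    sft=sft[i],
                    true_BT=bt[i],
                    true_BA=ba[i],
                    true_g=gfac[i],
                    true_MPI=mpi[i],
                    group=name,
                )
            )
            sid += 1
    table = pd.DataFrame(rows)

    if mode == "table":
        return table, None

    stacks = _render_cohort(spec, table, rng)
    return table, stacks


def _render_cohort(
    spec: CohortSpec, table: pd.DataFrame, rng: np.random.Generator
) -> list[SubjectStack]:
    """Render one multi-slice phantom stack per subject, realizing BT and g."""
    stacks = []
    marrow_intensity = 0.90
    for idx in table.index:
        row = table.loc[idx]
        bt = float(row.true_BT)
        g = float(row.true_g)
        d_out = 2 * bt / (1 - g)  # ring model: g = (d_out - 2 bt) / d_out
        phase = rng.uniform(0, 2 * np.pi)
        base = PhantomSpec(
            outer_diameter=d_out,
            wall_thickness=bt,
            deformation_harmonics=(
                ((3, spec.deformation_amplitude, phase),)
                if spec.deformation_amplitude > 0
                else ()
            ),
            intensity_bone=min(1.0, float(row.true_MPI) * marrow_intensity),
            intensity_marrow=marrow_intensity,
            noise_sd=spec.image_noise_sd,
            pixel_spacing=spec.pixel_spacing,
            supersample_factor=spec.supersample_factor,
        )
        grid = base.auto_grid_size()
        slices = []
        truths = []
        for k in range(spec.n_slices):
            scale = 1 + rng.uniform(-spec.slice_jitter, spec.slice_jitter)
            sl_spec = replace(
                base,
                outer_diameter=d_out * scale,
                wall_thickness=bt * scale,
                grid_size=grid,
            )
            img, bone, marrow, truth = make_annulus_phantom(sl_spec, rng=rng)
            img.slice_index = bone.slice_index = marrow.slice_index = k
            slices.append((img, bone, marrow))
            truths.append(truth)
        stacks.append(
            SubjectStack(
                subject_id=str(row.subject_id),
                slices=slices,
                age=float(row.age),
                sex=str(row.sex),
                bmi=float(row.bmi),
                mfi_class=str(row.mfi_class),
                sft=float(row.sft),
            )
        )
        # the rendered geometry determines BA/CL/BMA; record the subject-level
        # truth as the unjittered base geometry's truth
        base_truth = compute_truth(replace(base, grid_size=grid))
        table.loc[idx, "true_BA"] = base_truth.true_BA
        table.loc[idx, "true_CL"] = base_truth.true_CL
        table.loc[idx, "true_BMA"] = base_truth.true_BMA
        table.loc[idx, "true_D_out"] = base_truth.true_D_out
    return stacks
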