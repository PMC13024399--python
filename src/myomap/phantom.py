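"""Synthetic cardiac CTA phantoms and simulated reader panels.

The generator emulates the features of an arterial-phase, ECG-gated cardiac
CT angiogram that the deviation-map pipeline actually consumes: a bright
ellipsoidal left-ventricular blood pool (~350 HU), a surrounding myocardial
shell (~100 HU, ~10 mm thick), optional hypoattenuating lesions placed in a
coronary-territory wedge of the shell, i.i.d. Gaussian noise, and a
perturbed "automatic" copy of the myocardium mask at a target Dice overlap
against the truth mask.  Cohorts mix ST-elevation infarctions (transmural
lesions), non-ST-elevation infarctions (subendocardial lesions) and
lesion-free cases; a simulated reader panel turns a cohort plus per-reader
operating points into reading records for the multi-reader multi-case
statistics.

Everything is seeded and bit-reproducible: identical spec + seed yields
identical voxels, cohorts and reading records.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .colormap import CTVolume
from .seg_eval import dice

__all__ = [
    "PhantomSpec",
    "PhantomCase",
    "ReaderOperatingPoint",
    "generate_phantom",
    "perturb_mask",
    "generate_cohort",
    "sample_truth",
    "cohort_truth",
    "simulate_readers",
]

TERRITORIES = ("RCA", "LAD", "CX")

#: Wedge center angles in the short-axis (x-y) plane, degrees.  The +y
#: direction is taken as anterior: LAD supplies the anterior/septal wall,
#: RCA the inferior wall, CX the lateral wall.
_TERRITORY_ANGLE = {"LAD": 90.0, "CX": 0.0, "RCA": -90.0}
_WEDGE_HALF_ANGLE = 40.0  # degrees

#: Inner (endocardial) ellipsoid semi-axes as a fraction of the field of
#: view, used when the spec does not fix them in mm.  At the default
#: 64 x 1.5 mm = 96 mm field of view this gives roughly a 40 x 48 x 60 mm
#: ventricular cavity, a plausible end-diastolic left ventricle.
_INNER_AXES_FRAC = (0.21, 0.25, 0.31)


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic cardiac CTA volume.

    HU defaults mimic arterial-phase contrast: ventricular blood ~350 HU,
    healthy myocardium ~100 HU, surrounding soft tissue/fat ~-50 HU.  The
    default lesion offset of -80 HU is the upper end of the attenuation
    difference reported for acute infarction; subendocardial lesions occupy
    the inner half of the shell thickness, transmural lesions the full
    thickness.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size: tuple[float, float, float] = (1.5, 1.5, 1.5)
    blood_hu: float = 350.0
    myo_hu: float = 100.0
    background_hu: float = -50.0
    lesion_hu_offset: float = -80.0
    noise_sd: float = 10.0
    lesion_kind: str = "none"  # none | subendocardial | transmural
    territory: str = "none"  # RCA | LAD | CX | none
    seed: int = 0
    shell_mm: float = 10.0
    inner_axes_mm: tuple[float, float, float] | None = None
    auto_mask_dice: float = 0.973

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(int(n) < 16 for n in self.grid_shape):
            raise ValueError(f"grid_shape must be 3 axes of >= 16 voxels, got {self.grid_shape}")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.lesion_kind not in ("none", "subendocardial", "transmural"):
            raise ValueError(f"unknown lesion_kind {self.lesion_kind!r}")
        if self.territory not in TERRITORIES + ("none",):
            raise ValueError(f"unknown territory {self.territory!r}")
        if (self.lesion_kind == "none") != (self.territory == "none"):
            raise ValueError(
                "lesion_kind and territory must be 'none' together: a lesion needs a "
                f"territory and vice versa (got lesion_kind={self.lesion_kind!r}, "
                f"territory={self.territory!r})"
            )
        if self.shell_mm <= 0:
            raise ValueError("shell_mm must be positive")
        if not 0 < self.auto_mask_dice <= 1:
            raise ValueError("auto_mask_dice must be in (0, 1]")


@dataclass
class PhantomCase:
    """One synthetic case: volume, truth/auto masks, lesion and label."""

    case_id: str
    volume: CTVolume
    myo_mask_truth: np.ndarray
    myo_mask_auto: np.ndarray
    lesion_mask: np.ndarray
    adjudication: str  # STEMI | NSTEMI | none
    territory: str  # RCA | LAD | CX | none
    spec: PhantomSpec | None = None

    def __post_init__(self) -> None:
        shape = self.volume.shape
        for name in ("myo_mask_truth", "myo_mask_auto", "lesion_mask"):
            m = np.asarray(getattr(self, name)).astype(bool)
            if m.shape != shape:
                raise ValueError(f"{name} shape {m.shape} does not match volume {shape}")
            setattr(self, name, m)
        if np.any(self.lesion_mask & ~self.myo_mask_truth):
            raise ValueError("lesion_mask extends outside myo_mask_truth")
        if (self.adjudication == "none") != (not self.lesion_mask.any()):
            raise ValueError("adjudication 'none' must coincide with an empty lesion mask")

    @property
    def positive(self) -> bool:
        return self.adjudication in ("STEMI", "NSTEMI")


@dataclass(frozen=True)
class ReaderOperatingPoint:
    """Detection behavior of one simulated reader under one condition."""

    reader_id: str
    condition: str  # with_colormap | without_colormap
    sensitivity: float
    specificity: float

    def __post_init__(self) -> None:
        if self.condition not in ("with_colormap", "without_colormap"):
            raise ValueError(f"unknown condition {self.condition!r}")
        for name in ("sensitivity", "specificity"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")


def _ellipsoid_field(spec: PhantomSpec, axes_mm: Sequence[float]) -> np.ndarray:
    """Normalized ellipsoid radius: <= 1 inside the ellipsoid."""
    grids = []
    for n, vox, a in zip(spec.grid_shape, spec.voxel_size, axes_mm):
        coord = (np.arange(n) - (n - 1) / 2.0) * vox
        grids.append(coord / a)
    gx, gy, gz = np.meshgrid(*grids, indexing="ij", sparse=True)
    return np.sqrt(gx**2 + gy**2 + gz**2)


def _geometry(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Blood-pool and myocardial-shell masks for a spec."""
    fov = np.array(spec.grid_shape) * np.array(spec.voxel_size)
    if spec.inner_axes_mm is not None:
        inner = np.asarray(spec.inner_axes_mm, dtype=float)
    else:
        inner = fov * np.array(_INNER_AXES_FRAC)
    outer = inner + spec.shell_mm
    u_in = _ellipsoid_field(spec, inner)
    u_out = _ellipsoid_field(spec, outer)
    blood = u_in <= 1.0
    myo = (u_out <= 1.0) & ~blood
    if not blood.any() or not myo.any():
        raise ValueError("phantom geometry degenerate: empty blood pool or shell")
    return blood, myo


def _wedge(spec: PhantomSpec) -> np.ndarray:
    """Angular wedge of the short-axis plane for the spec's territory."""
    center = _TERRITORY_ANGLE[spec.territory]
    nx, ny, _ = spec.grid_shape
    vx, vy, _ = spec.voxel_size
    x = (np.arange(nx) - (nx - 1) / 2.0) * vx
    y = (np.arange(ny) - (ny - 1) / 2.0) * vy
    theta = np.degrees(np.arctan2(y[None, :], x[:, None]))  # (nx, ny)
    delta = (theta - center + 180.0) % 360.0 - 180.0
    return (np.abs(delta) <= _WEDGE_HALF_ANGLE)[:, :, None]


def generate_phantom(spec: PhantomSpec, case_id: str = "case") -> PhantomCase:
    """Generate one synthetic cardiac CTA case from a spec.

    The lesion, when requested, is the intersection of the myocardial shell
    with the territory wedge; subendocardial lesions are additionally
    restricted to voxels within half the shell thickness of the blood pool.
    Lesion voxels have mean attenuation ``myo_hu + lesion_hu_offset`` before
    noise.  Identical spec + seed reproduce the identical volume.
    """
    blood, myo = _geometry(spec)

    lesion = np.zeros(spec.grid_shape, dtype=bool)
    if spec.lesion_kind != "none":
        lesion = myo & _wedge(spec)
        if spec.lesion_kind == "subendocardial":
            depth = ndimage.distance_transform_edt(~blood, sampling=spec.voxel_size)
            lesion &= depth <= spec.shell_mm / 2.0
        if not lesion.any():
            raise ValueError(
                f"requested {spec.lesion_kind} lesion in {spec.territory} is empty on "
                f"this grid; enlarge grid_shape or voxel_size"
            )

    data = np.full(spec.grid_shape, spec.background_hu, dtype=float)
    data[myo] = spec.myo_hu
    data[blood] = spec.blood_hu
    data[lesion] += spec.lesion_hu_offset

    rng = np.random.default_rng(np.random.SeedSequence(int(spec.seed)))
    if spec.noise_sd > 0:
        data = data + rng.normal(0.0, spec.noise_sd, size=spec.grid_shape)

    auto_seed = int(np.random.SeedSequence(int(spec.seed)).generate_state(2)[1] % 2**31)
    auto = perturb_mask(myo, spec.auto_mask_dice, seed=auto_seed)

    adjudication = {"none": "none", "subendocardial": "NSTEMI", "transmural": "STEMI"}[
        spec.lesion_kind
    ]
    return PhantomCase(
        case_id=case_id,
        volume=CTVolume(data, spacing=tuple(spec.voxel_size)),
        myo_mask_truth=myo,
        myo_mask_auto=auto,
        lesion_mask=lesion,
        adjudication=adjudication,
        territory=spec.territory,
        spec=spec,
    )


def perturb_mask(
    mask: np.ndarray,
    target_dice: float,
    seed: int,
    tol: float = 0.005,
) -> np.ndarray:
    """Degrade a binary mask to a target Dice overlap against the original.

    Random boundary voxels are flipped one at a time — removals from the
    mask's inner boundary and additions on its outer boundary, chosen with
    equal probability — until the Dice score against the input first drops
    to the target.  Each flip moves Dice by ~1/|mask|, so on masks of a few
    thousand voxels the achieved score lies well within ``tol`` of the
    target.  ``target_dice=1`` returns a copy of the input unchanged.

    Raises ``ValueError`` if the target cannot be hit within ``tol`` (e.g.
    a mask so small that single flips overshoot the tolerance band).
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("mask is empty")
    if not 0.0 < target_dice <= 1.0:
        raise ValueError(f"target_dice must be in (0, 1], got {target_dice}")
    if target_dice == 1.0:
        return mask.copy()

    rng = np.random.default_rng(seed)
    out = mask.copy()
    n_a = int(mask.sum())
    inter = n_a
    n_b = n_a

    removable: list[int] = []
    addable: list[int] = []

    def refresh() -> None:
        inner = out & ~ndimage.binary_erosion(out)
        outer = ndimage.binary_dilation(out) & ~out
        removable[:] = list(rng.permutation(np.flatnonzero(inner.ravel())))
        addable[:] = list(rng.permutation(np.flatnonzero(outer.ravel())))

    refresh()
    flat = out.ravel()
    orig_flat = mask.ravel()
    current = 1.0
    max_flips = 20 * n_a
    for _ in range(max_flips):
        current = 2.0 * inter / (n_a + n_b)
        if current <= target_dice:
            break
        if not removable or not addable:
            refresh()
            if not removable and not addable:
                break
        do_remove = bool(rng.integers(2)) if (removable and addable) else bool(removable)
        if do_remove:
            idx = removable.pop()
            if not flat[idx]:
                continue
            flat[idx] = False
            n_b -= 1
            if orig_flat[idx]:
                inter -= 1
        else:
            idx = addable.pop()
            if flat[idx]:
                continue
            flat[idx] = True
            n_b += 1
            if orig_flat[idx]:
                inter += 1
    achieved = dice(mask, out)
    if abs(achieved - target_dice) > tol:
        raise ValueError(
            f"could not reach target Dice {target_dice} within +/-{tol}: achieved "
            f"{achieved:.4f} on a {n_a}-voxel mask"
        )
    return out


def _sample_labels(
    n_stemi: int, n_nstemi: int, n_none: int, rng: np.random.Generator
) -> list[tuple[str, str]]:
    """Shuffled (adjudication, territory) labels for a cohort."""
    labels = ["STEMI"] * n_stemi + ["NSTEMI"] * n_nstemi + ["none"] * n_none
    order = rng.permutation(len(labels))
    out = []
    for i in order:
        adjudication = labels[i]
        territory = "none" if adjudication == "none" else str(rng.choice(TERRITORIES))
        out.append((adjudication, territory))
    return out


def sample_truth(
    n_stemi: int, n_nstemi: int, n_none: int, seed: int = 0
) -> pd.DataFrame:
    """Adjudication table for a cohort without synthesizing any volumes.

    Returns columns ``case_id, adjudication, territory`` — exactly what the
    reader simulation and the MRMC statistics need — so that large
    parameter-recovery experiments do not pay for voxel synthesis.
    """
    rng = np.random.default_rng(np.random.SeedSequence(int(seed)))
    labels = _sample_labels(n_stemi, n_nstemi, n_none, rng)
    n = len(labels)
    width = max(3, len(str(n)))
    return pd.DataFrame(
        {
            "case_id": [f"case{idx + 1:0{width}d}" for idx in range(n)],
            "adjudication": [a for a, _ in labels],
            "territory": [t for _, t in labels],
        }
    )


def generate_cohort(
    n_stemi: int,
    n_nstemi: int,
    n_none: int,
    base_spec: PhantomSpec | None = None,
    seed: int = 0,
) -> list[PhantomCase]:
    """Generate a cohort of phantom cases matching a STEMI/NSTEMI/none mix.

    STEMI cases receive transmural lesions, NSTEMI cases subendocardial
    lesions, 'none' cases no lesion; culprit territories are drawn
    reproducibly from {RCA, LAD, CX}.  Case order is shuffled so lesion and
    non-lesion cases interleave as in a reading worklist.
    """
    for name, n in (("n_stemi", n_stemi), ("n_nstemi", n_nstemi), ("n_none", n_none)):
        if n < 0:
            raise ValueError(f"{name} must be >= 0")
    base = base_spec or PhantomSpec()
    truth = sample_truth(n_stemi, n_nstemi, n_none, seed=seed)
    case_seeds = np.random.SeedSequence(int(seed)).generate_state(len(truth) + 1)[1:]
    kind_for = {"STEMI": "transmural", "NSTEMI": "subendocardial", "none": "none"}
    cases = []
    for (_, row), cseed in zip(truth.iterrows(), case_seeds):
        spec = replace(
            base,
            lesion_kind=kind_for[row.adjudication],
            territory=row.territory,
            seed=int(cseed % 2**31),
        )
        cases.append(generate_phantom(spec, case_id=row.case_id))
    return cases


def cohort_truth(cohort: Iterable[PhantomCase]) -> pd.DataFrame:
    """Adjudication table (case_id, adjudication, territory) of a cohort."""
    return pd.DataFrame(
        {
            "case_id": [c.case_id for c in cohort],
            "adjudication": [c.adjudication for c in cohort],
            "territory": [c.territory for c in cohort],
        }
    )


#: Median reading time per condition (seconds) for the simulated panel and
#: the log-normal spread of times around it.
_TIME_MEDIAN_S = {"without_colormap": 27.0, "with_colormap": 25.0}
_TIME_LOG_SD = 0.5


def simulate_readers(
    cohort: Iterable[PhantomCase] | pd.DataFrame,
    points: Sequence[ReaderOperatingPoint],
    design,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a reader panel over a design, producing reading records.

    ``cohort`` may be a list of :class:`PhantomCase` or an adjudication
    table as produced by :func:`sample_truth`.  For each slot of the design
    the hypodense-myocardium rating is an independent coin with P(yes) =
    sensitivity on lesion cases and 1 - specificity on lesion-free cases,
    using the operating point of that slot's reader x condition.  Certainty
    is drawn on the side of the rating ('yes' ratings split between
    'probably yes' and 'definitively yes'); the assigned territory is the
    true culprit territory for true positives, a uniform draw for false
    positives, and 'none' whenever the rating is 'no'.  Reading times are
    log-normal around a per-condition median.

    Returns a reading-record table with columns ``session, reader_id,
    case_id, condition, hypodense, certainty, territory, time_s``.
    """
    if isinstance(cohort, pd.DataFrame):
        truth = cohort
    else:
        truth = cohort_truth(cohort)
    truth = truth.set_index("case_id")

    point_for = {(p.reader_id, p.condition): p for p in points}
    table = design.expand()
    needed = set(zip(table.reader_id, table.condition))
    missing = sorted(k for k in needed if k not in point_for)
    if missing:
        raise ValueError(f"missing operating points for reader x condition: {missing}")

    ss = np.random.SeedSequence(int(seed))
    groups = sorted(needed)
    children = dict(zip(groups, ss.spawn(len(groups))))

    chunks = []
    for key, sub in table.groupby(["reader_id", "condition"], sort=True):
        sub = sub.sort_values(["session", "case_id"]).reset_index(drop=True)
        rng = np.random.default_rng(children[key])
        op = point_for[key]
        t = truth.loc[sub.case_id]
        positive = t.adjudication.isin(["STEMI", "NSTEMI"]).to_numpy()
        p_yes = np.where(positive, op.sensitivity, 1.0 - op.specificity)
        yes = rng.random(len(sub)) < p_yes

        conf = rng.random(len(sub))
        certainty = np.where(
            yes,
            np.where(conf < 0.5, "prob_yes", "def_yes"),
            np.where(conf < 0.5, "prob_no", "def_no"),
        )

        random_terr = rng.choice(TERRITORIES, size=len(sub))
        true_terr = t.territory.to_numpy()
        territory = np.where(yes & positive, true_terr, np.where(yes, random_terr, "none"))

        median = _TIME_MEDIAN_S[key[1]]
        time_s = np.round(
            rng.lognormal(mean=np.log(median), sigma=_TIME_LOG_SD, size=len(sub)), 1
        )

        out = sub.copy()
        out["hypodense"] = np.where(yes, "yes", "no")
        out["certainty"] = certainty
        out["territory"] = territory
        out["time_s"] = time_s
        chunks.append(out)

    records = pd.concat(chunks, ignore_index=True)
    records = records.sort_values(["session", "reader_id", "case_id"]).reset_index(drop=True)
    return records[
        ["session", "reader_id", "case_id", "condition", "hypodense", "certainty", "territory", "time_s"]
    ]
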