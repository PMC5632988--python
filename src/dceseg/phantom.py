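"""Synthetic 4D DCE-MRI phantoms with known ground truth.

Each phantom is one slice of a dynamic series (default 96 x 96 voxels, 65
frames, contrast arriving after frame 8) populated by four tissue classes
with class-distinct enhancement curves:

* **vessel** — early, tall first pass (onset 9, peak 12, peak enhancement
  3.0) with strong washout;
* **tumor**  — slightly later, strong wash-in (onset 10, peak 20, peak 1.5)
  with a persistent plateau;
* **normal** — slow, shallow enhancement (onset 12, peak 40, peak 0.5);
* **cavity** — essentially non-enhancing air/fluid with a tiny baseline.

Templates are piecewise linear on the normalized scale (zero before onset,
linear rise to the peak, linear decay to the final frame), the simplest shape
that exercises every kinetic feature with analytically known values; a
gamma-variate shape is available as a non-default switch.  Raw intensities
are ``baseline * (1 + template)`` plus white Gaussian noise with SD
``noise_sd_rel * baseline`` per frame, floored at zero.  Per-voxel jitter
(amplitude and peak position) and per-sample archetype variation emulate
biological heterogeneity.  All randomness flows from one seed through
``numpy.random.SeedSequence`` spawning, so datasets are bit-reproducible.

Each sample carries one training ROI fully inside each class region, the
exact tumor ground-truth mask, and a rough rectangular search ROI around the
tumor for segmentation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .dataset import CLASS_ORDER, RoiRect, TissueClass
from .tic import DynamicSeries

__all__ = [
    "ClassArchetype",
    "PhantomSpec",
    "PhantomSample",
    "DEFAULT_ARCHETYPES",
    "noiseless_archetypes",
    "archetype_tic",
    "make_sample",
    "make_dataset",
    "generate_samples",
]


@dataclass(frozen=True)
class ClassArchetype:
    """The curve family of one tissue class.

    ``peak_enh`` and ``end_enh`` are on the normalized scale (relative
    enhancement over baseline); ``jitter_enh_rel`` is the per-voxel relative
    SD of the curve amplitude and ``jitter_peak_frames`` the per-voxel SD of
    the peak position in frames.
    """

    label: TissueClass
    baseline: float
    onset_frame: int
    peak_frame: int
    peak_enh: float
    end_enh: float
    jitter_enh_rel: float = 0.05
    jitter_peak_frames: float = 1.0
    shape: str = "linear"  # or "gamma"

    def __post_init__(self) -> None:
        if self.baseline <= 0:
            raise ValueError("baseline must be positive")
        if self.peak_frame < self.onset_frame:
            raise ValueError("peak_frame must be >= onset_frame")
        if self.peak_enh < self.end_enh:
            raise ValueError("peak_enh must be >= end_enh (washout shape)")
        if self.shape not in ("linear", "gamma"):
            raise ValueError(f"unknown template shape {self.shape!r}")


DEFAULT_ARCHETYPES: dict[TissueClass, ClassArchetype] = {
    TissueClass.VESSEL: ClassArchetype(
        TissueClass.VESSEL, baseline=100.0, onset_frame=9, peak_frame=12,
        peak_enh=3.0, end_enh=1.0,
    ),
    TissueClass.TUMOR: ClassArchetype(
        TissueClass.TUMOR, baseline=100.0, onset_frame=10, peak_frame=20,
        peak_enh=1.5, end_enh=1.2,
    ),
    TissueClass.NORMAL: ClassArchetype(
        TissueClass.NORMAL, baseline=100.0, onset_frame=12, peak_frame=40,
        peak_enh=0.5, end_enh=0.45,
    ),
    TissueClass.CAVITY: ClassArchetype(
        TissueClass.CAVITY, baseline=5.0, onset_frame=9, peak_frame=30,
        peak_enh=0.02, end_enh=0.01,
    ),
}


def noiseless_archetypes(
    archetypes: dict[TissueClass, ClassArchetype] | None = None,
) -> dict[TissueClass, ClassArchetype]:
    """The given (or default) archetypes with all per-voxel jitter removed."""
    archetypes = archetypes or DEFAULT_ARCHETYPES
    return {
        cls: replace(a, jitter_enh_rel=0.0, jitter_peak_frames=0.0)
        for cls, a in archetypes.items()
    }


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and noise settings of one synthetic sample."""

    nx: int = 96
    ny: int = 96
    n_frames: int = 65
    n_pre: int = 8
    noise_sd_rel: float = 0.03
    tumor_radius_range: tuple[int, int] = (9, 14)
    n_vessels_range: tuple[int, int] = (2, 4)
    vessel_radius_range: tuple[int, int] = (3, 5)
    cavity_size_range: tuple[int, int] = (10, 16)
    test_roi_margin: int = 4
    min_region_voxels: int = 20

    def __post_init__(self) -> None:
        if self.noise_sd_rel < 0:
            raise ValueError("noise_sd_rel must be >= 0")
        if not 1 <= self.n_pre < self.n_frames:
            raise ValueError("need 1 <= n_pre < n_frames")


@dataclass
class PhantomSample:
    """One synthetic sample: series, class-label mask, training ROIs, tumor
    ground truth, and the rough search ROI for segmentation."""

    series: DynamicSeries
    label_mask: np.ndarray  # (nx, ny, 1) int8, codes per _CLASS_CODES
    train_rois: list
    tumor_mask: np.ndarray  # (nx, ny, 1) bool
    test_roi: RoiRect


_CLASS_CODES = {
    TissueClass.NORMAL: 0,
    TissueClass.TUMOR: 1,
    TissueClass.VESSEL: 2,
    TissueClass.CAVITY: 3,
}
CODE_TO_CLASS = {v: k for k, v in _CLASS_CODES.items()}


def _template(
    onset: int, peak: int, peak_enh: float, end_enh: float, n_frames: int,
    shape: str = "linear",
) -> np.ndarray:
    """Normalized enhancement template on frames 1..n_frames."""
    t = np.arange(1, n_frames + 1, dtype=float)
    tpl = np.zeros(n_frames)
    if shape == "gamma":
        # gamma-variate: peak_enh * ((t-onset)/(peak-onset))^a * exp(a(1-(t-onset)/(peak-onset)))
        a = 2.0
        tau = np.clip(t - onset, 0.0, None) / max(peak - onset, 1)
        tpl = peak_enh * tau**a * np.exp(a * (1.0 - tau))
        # lift the tail toward end_enh so late-frame behaviour stays controllable
        tail = t > peak
        tpl[tail] = np.maximum(tpl[tail], end_enh)
        return tpl
    if peak > onset:
        rise = (t > onset) & (t <= peak)
        tpl[rise] = peak_enh * (t[rise] - onset) / (peak - onset)
    else:
        tpl[t == peak] = peak_enh
    if n_frames > peak:
        fall = t > peak
        tpl[fall] = peak_enh + (end_enh - peak_enh) * (t[fall] - peak) / (n_frames - peak)
    return tpl


def _class_curves(
    arch: ClassArchetype,
    n_vox: int,
    n_frames: int,
    noise_sd_rel: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Raw curves for ``n_vox`` voxels of one class, with per-voxel jitter."""
    if arch.jitter_peak_frames > 0:
        shifts = np.rint(rng.normal(0.0, arch.jitter_peak_frames, n_vox)).astype(int)
    else:
        shifts = np.zeros(n_vox, dtype=int)
    peaks = np.clip(arch.peak_frame + shifts, arch.onset_frame, n_frames)
    if arch.jitter_enh_rel > 0:
        amp = np.clip(1.0 + arch.jitter_enh_rel * rng.standard_normal(n_vox), 0.1, None)
    else:
        amp = np.ones(n_vox)

    curves = np.empty((n_vox, n_frames))
    for pk in np.unique(peaks):
        tpl = _template(arch.onset_frame, int(pk), arch.peak_enh, arch.end_enh,
                        n_frames, arch.shape)
        curves[peaks == pk] = tpl
    curves *= amp[:, None]

    raw = arch.baseline * (1.0 + curves)
    if noise_sd_rel > 0:
        raw = raw + rng.normal(0.0, noise_sd_rel * arch.baseline, (n_vox, n_frames))
    return np.maximum(raw, 0.0)


def archetype_tic(
    arch: ClassArchetype,
    n_frames: int,
    rng: np.random.Generator,
    noise_sd_rel: float = 0.0,
) -> np.ndarray:
    """One raw curve drawn from an archetype (jitter and noise applied)."""
    return _class_curves(arch, 1, n_frames, noise_sd_rel, rng)[0]


# --- geometry ---------------------------------------------------------------


def _disk(nx: int, ny: int, cx: int, cy: int, r: int) -> np.ndarray:
    X, Y = np.ogrid[:nx, :ny]
    return (X - cx) ** 2 + (Y - cy) ** 2 <= r**2


def _ellipse(nx: int, ny: int, cx: int, cy: int, rx: int, ry: int) -> np.ndarray:
    X, Y = np.ogrid[:nx, :ny]
    return ((X - cx) / rx) ** 2 + ((Y - cy) / ry) ** 2 <= 1.0


def _inner_rect(region: np.ndarray, cx: int, cy: int, half: int) -> RoiRect | None:
    """Largest centered square ROI (up to ``half``) fully inside ``region``."""
    nx, ny = region.shape
    for h in range(half, 1, -1):
        x0, x1 = cx - h, cx + h
        y0, y1 = cy - h, cy + h
        if x0 < 0 or y0 < 0 or x1 > nx or y1 > ny:
            continue
        if region[x0:x1, y0:y1].all():
            return RoiRect(0, x0, x1, y0, y1)
    return None


def _make_geometry(spec: PhantomSpec, rng: np.random.Generator):
    """Place cavity rectangle, tumor ellipse, and vessel disks on a normal
    background; returns (labels, per-class anchor info)."""
    nx, ny = spec.nx, spec.ny
    for _ in range(200):
        labels = np.zeros((nx, ny), dtype=np.int8)

        cw = int(rng.integers(spec.cavity_size_range[0], spec.cavity_size_range[1] + 1))
        ch = int(rng.integers(spec.cavity_size_range[0], spec.cavity_size_range[1] + 1))
        cx0 = int(rng.integers(2, nx - cw - 2))
        cy0 = int(rng.integers(2, ny - ch - 2))
        labels[cx0 : cx0 + cw, cy0 : cy0 + ch] = _CLASS_CODES[TissueClass.CAVITY]

        rx = int(rng.integers(spec.tumor_radius_range[0], spec.tumor_radius_range[1] + 1))
        ry = int(rng.integers(spec.tumor_radius_range[0], spec.tumor_radius_range[1] + 1))
        placed_tumor = None
        for _ in range(50):
            tcx = int(rng.integers(rx + 2, nx - rx - 2))
            tcy = int(rng.integers(ry + 2, ny - ry - 2))
            ell = _ellipse(nx, ny, tcx, tcy, rx, ry)
            if (labels[ell] == 0).all():
                labels[ell] = _CLASS_CODES[TissueClass.TUMOR]
                placed_tumor = (tcx, tcy, rx, ry, ell)
                break
        if placed_tumor is None:
            continue

        n_vessels = int(rng.integers(spec.n_vessels_range[0], spec.n_vessels_range[1] + 1))
        vessels = []
        ok = True
        for _ in range(n_vessels):
            placed = False
            for _ in range(50):
                r = int(rng.integers(spec.vessel_radius_range[0], spec.vessel_radius_range[1] + 1))
                vcx = int(rng.integers(r + 1, nx - r - 1))
                vcy = int(rng.integers(r + 1, ny - r - 1))
                disk = _disk(nx, ny, vcx, vcy, r)
                if (labels[disk] == 0).all():
                    labels[disk] = _CLASS_CODES[TissueClass.VESSEL]
                    vessels.append((vcx, vcy, r))
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if not ok:
            continue

        counts = np.bincount(labels.ravel(), minlength=4)
        if (counts < spec.min_region_voxels).any():
            continue
        return labels, placed_tumor, vessels, (cx0, cy0, cw, ch)
    raise RuntimeError("could not place disjoint phantom geometry; enlarge the grid")


def _train_rois(spec, labels, tumor, vessels, cavity, rng) -> list[RoiRect]:
    nx, ny = labels.shape
    rois = []

    tcx, tcy, rx, ry, _ = tumor
    half = max(2, int(min(rx, ry) / math.sqrt(2.0)))
    roi = _inner_rect(labels == _CLASS_CODES[TissueClass.TUMOR], tcx, tcy, half)
    rois.append(replace(roi, label=TissueClass.TUMOR))

    vcx, vcy, r = max(vessels, key=lambda v: v[2])
    half = max(2, int(r / math.sqrt(2.0)))
    roi = _inner_rect(labels == _CLASS_CODES[TissueClass.VESSEL], vcx, vcy, half)
    rois.append(replace(roi, label=TissueClass.VESSEL))

    cx0, cy0, cw, ch = cavity
    rois.append(
        RoiRect(0, cx0 + 1, cx0 + cw - 1, cy0 + 1, cy0 + ch - 1, TissueClass.CAVITY)
    )

    normal = labels == _CLASS_CODES[TissueClass.NORMAL]
    for _ in range(500):
        x0 = int(rng.integers(0, nx - 8))
        y0 = int(rng.integers(0, ny - 8))
        if normal[x0 : x0 + 8, y0 : y0 + 8].all():
            rois.append(RoiRect(0, x0, x0 + 8, y0, y0 + 8, TissueClass.NORMAL))
            break
    else:
        raise RuntimeError("no all-normal 8x8 window found for the normal ROI")

    order = {cls: i for i, cls in enumerate(CLASS_ORDER)}
    rois.sort(key=lambda roi: order[roi.label])
    return rois


def make_sample(
    spec: PhantomSpec,
    archetypes: dict[TissueClass, ClassArchetype],
    rng: np.random.Generator,
) -> PhantomSample:
    """Generate one phantom sample: geometry, voxel curves, ROIs, masks."""
    for cls in TissueClass:
        if cls not in archetypes:
            raise ValueError(f"missing archetype for class {cls.value}")
        if archetypes[cls].onset_frame <= spec.n_pre:
            raise ValueError(f"{cls.value} onset must be after frame n_pre={spec.n_pre}")

    labels, tumor, vessels, cavity = _make_geometry(spec, rng)
    rois = _train_rois(spec, labels, tumor, vessels, cavity, rng)

    data = np.empty((spec.nx, spec.ny, spec.n_frames))
    for cls in CLASS_ORDER:  # fixed order keeps the rng stream deterministic
        mask = labels == _CLASS_CODES[cls]
        data[mask] = _class_curves(
            archetypes[cls], int(mask.sum()), spec.n_frames, spec.noise_sd_rel, rng
        )
    series = DynamicSeries(data[:, :, None, :], n_pre=spec.n_pre)

    tcx, tcy, rx, ry, _ = tumor
    m = spec.test_roi_margin
    test_roi = RoiRect(
        0,
        max(0, tcx - rx - m),
        min(spec.nx, tcx + rx + m + 1),
        max(0, tcy - ry - m),
        min(spec.ny, tcy + ry + m + 1),
    )

    return PhantomSample(
        series=series,
        label_mask=labels[:, :, None],
        train_rois=rois,
        tumor_mask=(labels == _CLASS_CODES[TissueClass.TUMOR])[:, :, None],
        test_roi=test_roi,
    )


def _vary_archetype(arch: ClassArchetype, spec: PhantomSpec, rng: np.random.Generator,
                    enh_rel: float = 0.2, frame_sd: float = 1.5) -> ClassArchetype:
    """Per-sample biological variation of an archetype: amplitude scale and
    small shifts of the onset/peak frames."""
    scale = float(np.clip(1.0 + enh_rel * rng.standard_normal(), 0.6, 1.4))
    onset = int(arch.onset_frame + round(rng.normal(0.0, frame_sd)))
    onset = max(spec.n_pre + 1, onset)
    peak = int(arch.peak_frame + round(rng.normal(0.0, frame_sd)))
    peak = min(max(peak, onset), spec.n_frames)
    return replace(
        arch,
        onset_frame=onset,
        peak_frame=peak,
        peak_enh=arch.peak_enh * scale,
        end_enh=arch.end_enh * scale,
    )


def generate_samples(
    n: int,
    spec: PhantomSpec,
    seed_seq: np.random.SeedSequence,
    archetypes: dict[TissueClass, ClassArchetype] | None = None,
    vary_samples: bool = True,
):
    """Yield ``n`` seeded phantom samples one at a time (memory-friendly)."""
    archetypes = archetypes or DEFAULT_ARCHETYPES
    for child in seed_seq.spawn(n):
        rng = np.random.default_rng(child)
        if vary_samples:
            archs = {cls: _vary_archetype(a, spec, rng) for cls, a in archetypes.items()}
        else:
            archs = archetypes
        yield make_sample(spec, archs, rng)


def make_dataset(
    n_train: int = 80,
    n_test: int = 40,
    spec: PhantomSpec | None = None,
    seed: int = 0,
    archetypes: dict[TissueClass, ClassArchetype] | None = None,
    vary_samples: bool = True,
) -> tuple[list[PhantomSample], list[PhantomSample]]:
    """Generate a seeded train/test phantom dataset (default 80/40 samples)."""
    if n_train < 1 or n_test < 1:
        raise ValueError("n_train and n_test must be >= 1")
    spec = spec or PhantomSpec()
    ss = np.random.SeedSequence(seed)
    samples = list(
        generate_samples(n_train + n_test, spec, ss, archetypes, vary_samples)
    )
    return samples[:n_train], samples[n_train:]
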