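"""Synthetic chest-CT airway phantoms.

Real radiolucent-FBA cohorts are private hospital data, so this module
generates the study conditions synthetically: a parametric binary airway
tree rasterized into a CT-like volume (air-filled lumen ~ -1000 HU, a thin
soft-tissue wall, parenchyma-range background), corrupted with a Gaussian
point-spread blur and scanner noise. Positive (FBA) cases receive a
soft-tissue-density plug occluding one bronchus; the airway distal to the
plug collapses to parenchyma density and is removed from the ground-truth
mask — the foreign body is never a discrete radiopaque object, exactly the
radiolucent premise: the signal lives in airway morphology, not intensity.

Every artifact is a pure function of (spec, seed).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from lucent.core import CTVolume, save_mask

FBA = "FBA"
NFBA = "NFBA"


# --------------------------------------------------------------------------
# types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Segment:
    """One airway segment: a capsule from start to end (mm) of given radius."""

    start: tuple[float, float, float]
    end: tuple[float, float, float]
    radius_mm: float
    generation: int
    parent: int  # -1 for the root (trachea)


@dataclass
class AirwayTreeSkeleton:
    """Binary branching tree of capsule segments, breadth-first order.

    Invariants: exactly one root; each child's start equals its parent's end;
    radii strictly positive and non-increasing down the tree.
    """

    segments: list[Segment]
    root_direction: tuple[float, float, float] = (0.0, 0.0, -1.0)

    def __post_init__(self) -> None:
        roots = [i for i, s in enumerate(self.segments) if s.parent == -1]
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root segment, found {len(roots)}")
        for i, s in enumerate(self.segments):
            if s.radius_mm <= 0:
                raise ValueError(f"segment {i} has non-positive radius")
            if s.parent >= 0:
                p = self.segments[s.parent]
                if not np.allclose(s.start, p.end, atol=1e-6):
                    raise ValueError(f"segment {i} does not start at its parent's end")
                if s.radius_mm > p.radius_mm + 1e-9:
                    raise ValueError(f"segment {i} radius exceeds its parent's")

    def descendants(self, index: int) -> list[int]:
        """Indices of all segments in the sub-tree rooted strictly below index."""
        out, frontier = [], [index]
        while frontier:
            children = [i for i, s in enumerate(self.segments) if s.parent in frontier]
            out.extend(children)
            frontier = children
        return out


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic airway phantom.

    Geometry defaults follow bronchial morphometry: child/parent radius
    ratio 0.78 (close to Murray's-law 2^(-1/3) ~ 0.794), branch half-angle
    35 deg +/- 10 deg jitter, segment length ~3.2x its radius, branching
    plane rolled 90 deg per generation. HU classes sit inside the standard
    chest window [-1000, +400] so preprocessing is exercised non-trivially.
    """

    n_generations: int = 4
    branch_angle_deg: float = 35.0
    branch_angle_jitter_deg: float = 10.0
    trachea_radius_mm: float = 8.0
    trachea_length_mm: float = 30.0
    radius_ratio: float = 0.78
    length_radius_ratio: float = 3.2
    branch_roll_deg: float = 90.0
    volume_shape: tuple[int, int, int] = (128, 128, 128)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    hu_lumen: float = -1000.0
    hu_wall: float = -100.0
    hu_parenchyma: float = -820.0
    hu_plug: float = 40.0
    noise_sd_hu: float = 30.0
    psf_sigma_vox: float = 0.7
    plug_generations: tuple[int, int] = (2, 3)  # inclusive range of plug sites
    plug_length_range_mm: tuple[float, float] = (3.0, 8.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")
        if not (self.hu_lumen < self.hu_parenchyma < self.hu_plug):
            raise ValueError("require hu_lumen < hu_parenchyma < hu_plug")
        for v in (self.hu_lumen, self.hu_wall, self.hu_parenchyma, self.hu_plug):
            if not -1024.0 <= v <= 1024.0:
                raise ValueError(f"HU value {v} outside [-1024, 1024]")
        if not 0.0 < self.radius_ratio < 1.0:
            raise ValueError("radius_ratio must be in (0, 1)")
        if self.trachea_radius_mm <= 0:
            raise ValueError("trachea_radius_mm must be positive")


@dataclass
class PhantomRecord:
    """One synthetic patient: volume, ground-truth mask, label, provenance."""

    patient_id: str
    volume: CTVolume
    mask: np.ndarray
    label: str
    obstruction: tuple[int, float] | None  # (segment index, plug length mm)
    seed: int

    def __post_init__(self) -> None:
        if (self.label == FBA) != (self.obstruction is not None):
            raise ValueError("label is FBA iff an obstruction is present")
        if not self.mask.any():
            raise ValueError("mask is empty")
        if self.mask.shape != self.volume.shape:
            raise ValueError("mask/volume shape mismatch")


# --------------------------------------------------------------------------
# tree generation
# --------------------------------------------------------------------------


def _rotate(v: np.ndarray, axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation of v about unit axis."""
    k = axis / np.linalg.norm(axis)
    return (v * np.cos(angle_rad)
            + np.cross(k, v) * np.sin(angle_rad)
            + k * np.dot(k, v) * (1.0 - np.cos(angle_rad)))


def _perpendicular(d: np.ndarray) -> np.ndarray:
    """A unit vector perpendicular to d (deterministic choice)."""
    ref = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    p = np.cross(d, ref)
    return p / np.linalg.norm(p)


def generate_tree(spec: PhantomSpec) -> AirwayTreeSkeleton:
    """Generate a binary airway tree with ``n_generations`` levels below the trachea.

    Deterministic given ``spec.seed``; segments are stored breadth-first.
    Raises if any segment (dilated by its radius) leaves the volume bounds,
    naming the first offending segment.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xA1]))
    extent = np.array(spec.volume_shape) * np.array(spec.spacing_mm)
    root_dir = np.array([0.0, 0.0, -1.0])
    top = np.array([extent[0] / 2.0, extent[1] / 2.0,
                    extent[2] - spec.trachea_radius_mm - 2.0 * spec.spacing_mm[2]])

    segments: list[Segment] = [Segment(tuple(top), tuple(top + root_dir * spec.trachea_length_mm),
                                       spec.trachea_radius_mm, 0, -1)]
    frontier = [(0, root_dir)]
    for gen in range(1, spec.n_generations + 1):
        radius = spec.trachea_radius_mm * spec.radius_ratio ** gen
        length = spec.length_radius_ratio * radius
        nxt = []
        for parent_idx, pdir in frontier:
            parent = segments[parent_idx]
            perp = _perpendicular(pdir)
            roll = np.deg2rad(spec.branch_roll_deg * gen
                              + rng.uniform(-15.0, 15.0) * (spec.branch_angle_jitter_deg > 0))
            axis = _rotate(perp, pdir, roll)
            for sign in (+1.0, -1.0):
                ang = spec.branch_angle_deg + rng.uniform(
                    -spec.branch_angle_jitter_deg, spec.branch_angle_jitter_deg)
                cdir = _rotate(pdir, axis, sign * np.deg2rad(ang))
                cdir = cdir / np.linalg.norm(cdir)
                end = np.array(parent.end) + cdir * length
                segments.append(Segment(parent.end, tuple(end), radius, gen, parent_idx))
                nxt.append((len(segments) - 1, cdir))
        frontier = nxt

    for i, s in enumerate(segments):
        for pt in (s.start, s.end):
            lo = np.array(pt) - s.radius_mm
            hi = np.array(pt) + s.radius_mm
            if (lo < 0).any() or (hi > extent).any():
                raise ValueError(
                    f"segment {i} (generation {s.generation}) leaves the volume "
                    f"bounds: point {pt} with radius {s.radius_mm:.2f} mm "
                    f"vs extent {tuple(extent)} mm")
    return AirwayTreeSkeleton(segments, tuple(root_dir))


# --------------------------------------------------------------------------
# rasterization
# --------------------------------------------------------------------------


def _capsule_mask(shape, spacing, seg: Segment, frac: float = 1.0) -> np.ndarray:
    """Voxels within seg.radius of the segment's first ``frac`` of its axis."""
    if seg.radius_mm <= 0:
        raise ValueError("degenerate (zero-radius) segment")
    a = np.array(seg.start)
    b = a + (np.array(seg.end) - a) * frac
    r = seg.radius_mm
    sp = np.array(spacing)
    lo = np.maximum(np.floor((np.minimum(a, b) - r) / sp - 0.5).astype(int), 0)
    hi = np.minimum(np.ceil((np.maximum(a, b) + r) / sp + 0.5).astype(int) + 1,
                    np.array(shape))
    if (hi <= lo).any():
        return np.zeros(shape, dtype=bool)
    grids = np.meshgrid(*[(np.arange(l, h) + 0.5) * s for l, h, s in zip(lo, hi, sp)],
                        indexing="ij")
    pts = np.stack(grids, axis=-1)
    ab = b - a
    denom = float(ab @ ab)
    if denom < 1e-12:
        d2 = ((pts - a) ** 2).sum(-1)
    else:
        t = np.clip(((pts - a) @ ab) / denom, 0.0, 1.0)
        d2 = ((pts - a - t[..., None] * ab) ** 2).sum(-1)
    sub = d2 <= r * r
    out = np.zeros(shape, dtype=bool)
    out[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = sub
    return out


def _skeleton_mask(tree: AirwayTreeSkeleton, spec: PhantomSpec,
                   shorten: dict[int, float] | None = None,
                   drop: set[int] | None = None) -> np.ndarray:
    """Union-of-capsules mask; optionally shorten/drop segments (for plugs)."""
    mask = np.zeros(spec.volume_shape, dtype=bool)
    for i, seg in enumerate(tree.segments):
        if drop and i in drop:
            continue
        frac = shorten.get(i, 1.0) if shorten else 1.0
        if frac <= 0.0:
            continue
        mask |= _capsule_mask(spec.volume_shape, spec.spacing_mm, seg, frac)
    return mask


def _corrupt(hu: np.ndarray, spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.psf_sigma_vox > 0:
        hu = ndimage.gaussian_filter(hu, spec.psf_sigma_vox)
    if spec.noise_sd_hu > 0:
        hu = hu + rng.normal(0.0, spec.noise_sd_hu, hu.shape).astype(np.float32)
    return hu.astype(np.float32)


def _clean_volume(mask: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Uncorrupted HU volume: parenchyma background, 1-voxel wall shell, lumen."""
    hu = np.full(spec.volume_shape, spec.hu_parenchyma, dtype=np.float32)
    shell = ndimage.binary_dilation(mask) & ~mask
    hu[shell] = spec.hu_wall
    hu[mask] = spec.hu_lumen
    return hu


def rasterize_phantom(tree: AirwayTreeSkeleton, spec: PhantomSpec,
                      corrupt: bool = True) -> tuple[CTVolume, np.ndarray]:
    """Rasterize a tree into (CT volume, airway mask).

    The mask is the union of capsules around the segments; the volume is
    parenchyma background with a 1-voxel airway wall and air-density lumen,
    then (if ``corrupt``) blurred with the PSF and corrupted with additive
    Gaussian noise. The noise stream is derived from ``spec.seed``.
    """
    mask = _skeleton_mask(tree, spec)
    hu = _clean_volume(mask, spec)
    if corrupt:
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xB2]))
        hu = _corrupt(hu, spec, rng)
    vol = CTVolume(hu, spacing_mm=spec.spacing_mm)
    return vol, mask


def plant_foreign_body(volume: CTVolume, mask: np.ndarray, tree: AirwayTreeSkeleton,
                       segment_index: int, plug_length_mm: float, spec: PhantomSpec,
                       patient_id: str = "phantom", corrupt: bool = True,
                       record_seed: int | None = None) -> PhantomRecord:
    """Plant a radiolucent foreign body into an (uncorrupted) phantom.

    The plug occupies ``plug_length_mm`` of the chosen segment starting at
    30% of its length: lumen voxels there take soft-tissue density
    (``hu_plug``). The airway distal to the plug collapses: distal lumen
    voxels revert to parenchyma density and the ground-truth mask is
    truncated at the plug (the obstructed sub-tree is un-segmentable).

    ``volume`` must be the uncorrupted rasterization of ``tree``; blur and
    noise are applied here when ``corrupt`` is true.
    """
    seg = tree.segments[segment_index]
    if seg.parent == -1:
        raise ValueError("cannot plug the trachea (root segment)")
    seg_len = float(np.linalg.norm(np.array(seg.end) - np.array(seg.start)))
    if plug_length_mm >= seg_len:
        raise ValueError(f"plug length {plug_length_mm} mm >= segment length {seg_len:.1f} mm")
    f0 = 0.3
    f1 = min(1.0, f0 + plug_length_mm / seg_len)

    # mask truncated at the plug: shorten the plugged segment, drop descendants
    drop = set(tree.descendants(segment_index))
    kept = _skeleton_mask(tree, spec, shorten={segment_index: f0}, drop=drop)
    plug_zone = _capsule_mask(spec.volume_shape, spec.spacing_mm, seg, f1) & ~_capsule_mask(
        spec.volume_shape, spec.spacing_mm, seg, f0)

    hu = volume.voxels.copy()
    distal = mask & ~kept
    hu[distal] = spec.hu_parenchyma          # collapsed (atelectatic) distal airway
    hu[plug_zone & mask] = spec.hu_plug      # the radiolucent plug itself
    if corrupt:
        rs = spec.seed if record_seed is None else record_seed
        rng = np.random.default_rng(np.random.SeedSequence([rs, 0xB2]))
        hu = _corrupt(hu, spec, rng)
    new_mask = mask & kept
    return PhantomRecord(patient_id, volume.with_voxels(hu), new_mask, FBA,
                         (segment_index, float(plug_length_mm)),
                         spec.seed if record_seed is None else record_seed)


# --------------------------------------------------------------------------
# cohorts
# --------------------------------------------------------------------------


def _record_seed(cohort_seed: int, i: int) -> int:
    # counter-based derivation so each record is independently reproducible
    return int(np.random.SeedSequence([cohort_seed, i]).generate_state(1)[0] % (2 ** 31))


def _make_record(spec: PhantomSpec, label: str, patient_id: str, seed: int) -> PhantomRecord:
    rspec = replace(spec, seed=seed)
    tree = generate_tree(rspec)
    if label == NFBA:
        vol, mask = rasterize_phantom(tree, rspec, corrupt=True)
        return PhantomRecord(patient_id, vol, mask, NFBA, None, seed)
    vol, mask = rasterize_phantom(tree, rspec, corrupt=False)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC3]))
    glo, ghi = rspec.plug_generations
    ghi = min(ghi, rspec.n_generations)
    gen = int(rng.integers(glo, ghi + 1))
    candidates = [i for i, s in enumerate(tree.segments) if s.generation == gen]
    seg_idx = int(rng.choice(candidates))
    seg = tree.segments[seg_idx]
    seg_len = float(np.linalg.norm(np.array(seg.end) - np.array(seg.start)))
    lo, hi = rspec.plug_length_range_mm
    plug_len = float(min(rng.uniform(lo, hi), 0.6 * seg_len))
    return plant_foreign_body(vol, mask, tree, seg_idx, plug_len, rspec,
                              patient_id=patient_id, corrupt=True, record_seed=seed)


def make_cohort(n_fba: int, n_nfba: int, spec: PhantomSpec, seed: int,
                out_dir: str | Path | None = None) -> list[PhantomRecord]:
    """Generate a labelled phantom cohort, reproducible from ``seed``.

    FBA records receive a randomly sited/sized obstruction; NFBA records do
    not. If ``out_dir`` is given, volumes and masks are written as NIfTI and
    a manifest CSV (patient_id, volume_path, mask_path, label, seed).
    """
    if n_fba < 0 or n_nfba < 0:
        raise ValueError("counts must be >= 0")
    records: list[PhantomRecord] = []
    labels = [FBA] * n_fba + [NFBA] * n_nfba
    for i, label in enumerate(labels):
        pid = f"P{i:04d}"
        records.append(_make_record(spec, label, pid, _record_seed(seed, i)))
    if out_dir is not None:
        write_cohort(records, out_dir)
    return records


def write_cohort(records: list[PhantomRecord], out_dir: str | Path) -> Path:
    """Write volumes/masks as .nii.gz plus a manifest CSV; returns manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "volume_path", "mask_path", "label", "seed"])
        for rec in records:
            vp = out / f"{rec.patient_id}_ct.nii.gz"
            mp = out / f"{rec.patient_id}_mask.nii.gz"
            rec.volume.to_nifti(vp)
            save_mask(rec.mask, rec.volume.spacing_mm, mp)
            w.writerow([rec.patient_id, vp.name, mp.name, rec.label, rec.seed])
    return manifest
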