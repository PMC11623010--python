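"""Seeded generator of SISH-like regions with exhaustive ground truth.

Renders the appearance model of a brightfield SISH region: a light
eosin-toned background, bluish-purple elliptical nuclei, black HER2 dots
and red CEP17 dots planted inside nuclei with known per-nucleus counts.
Probe clusters are rendered as single disks of k-fold area with recorded
multiplicity, faint dots at reduced contrast, and nuclei can be planted
across the image border (truncated) or as >50 %-overlapping pairs.  Every
scene ships with a machine-readable ground truth, so detection, counting,
qualification, and scoring are all testable without any external data.

Appearance constants are spec fields, chosen so the default detection
configuration recovers planted dots; none are hard-coded in the pipeline.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
from skimage import draw

from .preprocess import RoiImage

# default palette, float RGB in [0, 1]
BACKGROUND_RGB = (0.96, 0.95, 0.94)
NUCLEUS_RGB = (0.58, 0.50, 0.74)
HER2_RGB = (0.08, 0.08, 0.09)
HER2_FAINT_RGB = (0.28, 0.28, 0.29)
CEP17_RGB = (0.70, 0.15, 0.19)
CEP17_FAINT_RGB = (0.78, 0.42, 0.45)


@dataclass
class SyntheticSpec:
    """Scene parameters.

    Count distributions are ``("fixed", k)``, ``("uniform", lo, hi)`` or
    ``("poisson_floor", lam, floor)``; they emulate normal (≈2/2),
    amplified (HER2 ≫ CEP17) and borderline regions.
    """

    image_size: tuple[int, int] = (640, 640)
    resolution_um_per_px: float = 0.13
    n_nuclei: int = 25
    nucleus_radius_um: tuple[float, float] = (4.5, 0.3)
    per_nucleus_her2: tuple = ("fixed", 2)
    per_nucleus_cep17: tuple = ("fixed", 2)
    dot_radius_um: float = 0.45
    cluster_probability: float = 0.0
    cluster_multiplicities: tuple[int, ...] = (2, 3, 4)
    faint_fraction: float = 0.0
    edge_clip_fraction: float = 0.0
    overlap_pair_fraction: float = 0.0
    eccentricity_max: float = 0.10
    noise_sd: float = 0.0  # Gaussian noise on the 8-bit scale
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("cluster_probability", "faint_fraction",
                     "edge_clip_fraction", "overlap_pair_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")
        if self.nucleus_radius_um[0] <= 0 or self.dot_radius_um <= 0:
            raise ValueError("radius parameters must be positive")


@dataclass
class DotTruth:
    center_rc: tuple[float, float]
    radius_um: float
    faint: bool = False
    multiplicity: int = 1


@dataclass
class NucleusTruth:
    center_rc: tuple[float, float]
    axes_px: tuple[float, float]  # (row semi-axis, col semi-axis)
    angle_deg: float
    her2_dots: list[DotTruth] = field(default_factory=list)
    cep17_dots: list[DotTruth] = field(default_factory=list)
    truncated: bool = False
    overlap_partner: int | None = None  # index of the paired nucleus

    @property
    def her2_count(self) -> int:
        return sum(d.multiplicity for d in self.her2_dots)

    @property
    def cep17_count(self) -> int:
        return sum(d.multiplicity for d in self.cep17_dots)


@dataclass
class GroundTruth:
    image_id: str
    image_size: tuple[int, int]
    resolution_um_per_px: float
    nuclei: list[NucleusTruth] = field(default_factory=list)
    expected_total_her2: int = 0
    expected_total_cep17: int = 0
    expected_ratio: float = 0.0
    expected_status: str = "Negative"
    expected_fallback: bool = False

    def qualifying_indices(self, min_cep17: int = 2) -> tuple[list[int], bool]:
        """Indices of interior, non-overlapped nuclei passing the CEP17 rule
        (with the single-CEP17 fallback); mirrors the pipeline filters."""
        eligible = [
            i for i, n in enumerate(self.nuclei)
            if not n.truncated and n.overlap_partner is None
        ]
        strict = [i for i in eligible if self.nuclei[i].cep17_count >= min_cep17]
        if strict:
            return strict, False
        return [i for i in eligible if self.nuclei[i].cep17_count >= 1], True


def sample_count(dist: tuple, rng: np.random.Generator) -> int:
    kind = dist[0]
    if kind == "fixed":
        return int(dist[1])
    if kind == "uniform":
        return int(rng.integers(int(dist[1]), int(dist[2]) + 1))
    if kind == "poisson_floor":
        return int(max(int(dist[2]), rng.poisson(float(dist[1]))))
    raise ValueError(f"unknown count distribution {dist!r}")


def _place_dots(
    nucleus: NucleusTruth,
    n_dots: int,
    dot_radii_px: list[float],
    rng: np.random.Generator,
    existing: list[tuple[float, float, float]],
    max_attempts: int = 1000,
) -> list[tuple[float, float]]:
    """Rejection-sample dot centers inside the nucleus ellipse, keeping a
    >= 2 px gap between dots so components stay separate."""
    (cr, cc) = nucleus.center_rc
    ar, ac = nucleus.axes_px
    theta = np.deg2rad(nucleus.angle_deg)
    placed: list[tuple[float, float]] = []
    for i in range(n_dots):
        rd = dot_radii_px[i]
        f_max = max(0.05, 1.0 - (rd + 3.0) / min(ar, ac))
        for _ in range(max_attempts):
            t = rng.uniform(0, 2 * np.pi)
            f = np.sqrt(rng.uniform()) * f_max
            u, v = f * ar * np.cos(t), f * ac * np.sin(t)
            dr = u * np.cos(theta) - v * np.sin(theta)
            dc = u * np.sin(theta) + v * np.cos(theta)
            r, c = cr + dr, cc + dc
            ok = all(
                np.hypot(r - pr, c - pc) >= rd + prad + 2.5
                for pr, pc, prad in existing
            )
            if ok:
                placed.append((r, c))
                existing.append((r, c, rd))
                break
        else:
            raise ValueError(
                "could not place probe dots without contact; reduce counts or "
                "enlarge the nucleus radius"
            )
    return placed


def generate_roi(spec: SyntheticSpec, image_id: str = "synthetic") -> tuple[RoiImage, GroundTruth]:
    """Render a scene and its ground truth.  Identical spec + seed give a
    bit-identical image and truth."""
    rng = np.random.default_rng(spec.seed)
    H, W = spec.image_size
    res = spec.resolution_um_per_px
    r_mean_px = spec.nucleus_radius_um[0] / res
    r_sd_px = spec.nucleus_radius_um[1] / res
    dot_r_px = spec.dot_radius_um / res

    n = spec.n_nuclei
    n_edge = int(round(spec.edge_clip_fraction * n))
    n_pairs = int(round(spec.overlap_pair_fraction * n / 2))
    n_interior = n - n_edge - 2 * n_pairs
    if n_interior < 0:
        raise ValueError("edge_clip_fraction + overlap_pair_fraction exceed n_nuclei")

    placed: list[tuple[float, float, float]] = []  # (row, col, keep-out radius)
    nuclei: list[NucleusTruth] = []

    def radius() -> float:
        return max(6.0, rng.normal(r_mean_px, r_sd_px))

    def far_enough(r, c, rad) -> bool:
        return all(np.hypot(r - pr, c - pc) >= rad + prad + 6 for pr, pc, prad in placed)

    def try_place(sampler, rad, attempts=600) -> tuple[float, float]:
        for _ in range(attempts):
            r, c = sampler()
            if far_enough(r, c, rad):
                return r, c
        raise ValueError(
            "infeasible nucleus packing; reduce n_nuclei or enlarge image_size"
        )

    def make_nucleus(r, c, rad, truncated=False, partner=None) -> NucleusTruth:
        ecc = rng.uniform(0, spec.eccentricity_max)
        ar, ac = rad * (1 + ecc), rad / (1 + ecc)
        return NucleusTruth(
            center_rc=(float(r), float(c)),
            axes_px=(float(ar), float(ac)),
            angle_deg=float(rng.uniform(0, 180)),
            truncated=truncated,
            overlap_partner=partner,
        )

    # interior singles
    for _ in range(n_interior):
        rad = radius()
        margin = rad * 1.15 + 4
        r, c = try_place(
            lambda: (rng.uniform(margin, H - margin), rng.uniform(margin, W - margin)),
            rad,
        )
        placed.append((r, c, rad))
        nuclei.append(make_nucleus(r, c, rad))

    # edge-clipped nuclei: center close enough to a border that the ellipse
    # is cut by it
    for _ in range(n_edge):
        rad = radius()

        def edge_sampler():
            side = rng.integers(4)
            off = rng.uniform(0.1, 0.4) * rad
            along = rng.uniform(rad, (W if side < 2 else H) - rad)
            if side == 0:
                return off, along
            if side == 1:
                return H - 1 - off, along
            if side == 2:
                return along, off
            return along, W - 1 - off

        r, c = try_place(edge_sampler, rad)
        placed.append((r, c, rad))
        nuclei.append(make_nucleus(r, c, rad, truncated=True))

    # overlapping pairs: equal circles at 0.6 r separation overlap by ~62 %
    # of each area, beyond the 50 % exclusion bound
    for _ in range(n_pairs):
        rad = radius()
        margin = rad * 1.8 + 4
        r, c = try_place(
            lambda: (rng.uniform(margin, H - margin), rng.uniform(margin, W - margin)),
            rad * 1.4,
        )
        t = rng.uniform(0, 2 * np.pi)
        d = 0.6 * rad
        r1, c1 = r - d / 2 * np.cos(t), c - d / 2 * np.sin(t)
        r2, c2 = r + d / 2 * np.cos(t), c + d / 2 * np.sin(t)
        placed.append((r, c, rad * 1.4))
        i1 = len(nuclei)
        n1 = NucleusTruth((float(r1), float(c1)), (rad, rad), 0.0,
                          overlap_partner=i1 + 1)
        n2 = NucleusTruth((float(r2), float(c2)), (rad, rad), 0.0,
                          overlap_partner=i1)
        nuclei.extend([n1, n2])

    # plant probe dots
    for nuc in nuclei:
        n_her2 = sample_count(spec.per_nucleus_her2, rng)
        n_cep17 = sample_count(spec.per_nucleus_cep17, rng)
        dot_existing: list[tuple[float, float, float]] = []
        # one HER2 dot may become a cluster of k merged probes
        her2_items: list[tuple[float, int]] = []  # (radius_px, multiplicity)
        remaining = n_her2
        if remaining >= 2 and rng.uniform() < spec.cluster_probability:
            k = int(rng.choice(spec.cluster_multiplicities))
            k = min(k, remaining)
            her2_items.append((dot_r_px * np.sqrt(k), k))
            remaining -= k
        her2_items.extend((dot_r_px, 1) for _ in range(remaining))
        radii = [it[0] for it in her2_items]
        centers = _place_dots(nuc, len(her2_items), radii, rng, dot_existing)
        for (r, c), (rad_px, k) in zip(centers, her2_items):
            faint = bool(k == 1 and rng.uniform() < spec.faint_fraction)
            nuc.her2_dots.append(
                DotTruth((float(r), float(c)), rad_px * res, faint, k)
            )
        radii = [dot_r_px] * n_cep17
        centers = _place_dots(nuc, n_cep17, radii, rng, dot_existing)
        for r, c in centers:
            faint = bool(rng.uniform() < spec.faint_fraction)
            nuc.cep17_dots.append(
                DotTruth((float(r), float(c)), dot_r_px * res, faint, 1)
            )

    # render
    img = np.empty((H, W, 3), dtype=np.float64)
    img[...] = BACKGROUND_RGB
    for nuc in nuclei:
        jitter = rng.normal(0, 0.015, size=3)
        color = np.clip(np.asarray(NUCLEUS_RGB) + jitter, 0, 1)
        rr, cc = draw.ellipse(
            nuc.center_rc[0], nuc.center_rc[1],
            nuc.axes_px[0], nuc.axes_px[1],
            shape=(H, W), rotation=np.deg2rad(nuc.angle_deg),
        )
        img[rr, cc] = color
    for nuc in nuclei:
        for dot, faint_rgb, rgb in (
            [(d, HER2_FAINT_RGB, HER2_RGB) for d in nuc.her2_dots]
            + [(d, CEP17_FAINT_RGB, CEP17_RGB) for d in nuc.cep17_dots]
        ):
            rr, cc = draw.disk(
                dot.center_rc, dot.radius_um / res, shape=(H, W)
            )
            img[rr, cc] = faint_rgb if dot.faint else rgb

    px = img * 255.0
    if spec.noise_sd > 0:
        px = px + rng.normal(0, spec.noise_sd, size=px.shape)
    px = np.clip(np.floor(px + 0.5), 0, 255).astype(np.uint8)
    roi = RoiImage(px, res, image_id)

    truth = GroundTruth(
        image_id=image_id,
        image_size=(H, W),
        resolution_um_per_px=res,
        nuclei=nuclei,
    )
    idx, fallback = truth.qualifying_indices()
    truth.expected_total_her2 = sum(nuclei[i].her2_count for i in idx)
    truth.expected_total_cep17 = sum(nuclei[i].cep17_count for i in idx)
    truth.expected_fallback = fallback
    if truth.expected_total_cep17 > 0:
        truth.expected_ratio = truth.expected_total_her2 / truth.expected_total_cep17
    truth.expected_status = (
        "Positive" if truth.expected_ratio >= 2.0 else "Negative"
    )
    return roi, truth


def rasterize_nucleus(nuc: NucleusTruth, shape: tuple[int, int]) -> np.ndarray:
    """Boolean full-frame mask of one planted nucleus ellipse."""
    mask = np.zeros(shape, dtype=bool)
    rr, cc = draw.ellipse(
        nuc.center_rc[0], nuc.center_rc[1], nuc.axes_px[0], nuc.axes_px[1],
        shape=shape, rotation=np.deg2rad(nuc.angle_deg),
    )
    mask[rr, cc] = True
    return mask


# ---------------------------------------------------------------------------
# truth serialization

def write_truth(truth: GroundTruth, path) -> None:
    with open(path, "w") as fh:
        json.dump(asdict(truth), fh, indent=1)


def _dot_from_dict(d: dict, where: str) -> DotTruth:
    if d["radius_um"] <= 0:
        raise ValueError(f"{where}.radius_um must be positive, got {d['radius_um']}")
    if d["multiplicity"] < 1:
        raise ValueError(f"{where}.multiplicity must be >= 1")
    return DotTruth(tuple(d["center_rc"]), d["radius_um"], d["faint"], d["multiplicity"])


def read_truth(path) -> GroundTruth:
    with open(path) as fh:
        doc = json.load(fh)
    try:
        nuclei = []
        for i, nd in enumerate(doc["nuclei"]):
            if min(nd["axes_px"]) <= 0:
                raise ValueError(f"nuclei[{i}].axes_px must be positive")
            nuc = NucleusTruth(
                center_rc=tuple(nd["center_rc"]),
                axes_px=tuple(nd["axes_px"]),
                angle_deg=nd["angle_deg"],
                her2_dots=[
                    _dot_from_dict(d, f"nuclei[{i}].her2_dots[{j}]")
                    for j, d in enumerate(nd["her2_dots"])
                ],
                cep17_dots=[
                    _dot_from_dict(d, f"nuclei[{i}].cep17_dots[{j}]")
                    for j, d in enumerate(nd["cep17_dots"])
                ],
                truncated=nd["truncated"],
                overlap_partner=nd["overlap_partner"],
            )
            nuclei.append(nuc)
        return GroundTruth(
            image_id=doc["image_id"],
            image_size=tuple(doc["image_size"]),
            resolution_um_per_px=doc["resolution_um_per_px"],
            nuclei=nuclei,
            expected_total_her2=doc["expected_total_her2"],
            expected_total_cep17=doc["expected_total_cep17"],
            expected_ratio=doc["expected_ratio"],
            expected_status=doc["expected_status"],
            expected_fallback=doc["expected_fallback"],
        )
    except KeyError as exc:
        raise ValueError(f"ground-truth document missing field {exc}") from exc


# ---------------------------------------------------------------------------
# presets emulating the study's scene classes

PRESETS: dict[str, SyntheticSpec] = {
    "normal": SyntheticSpec(
        n_nuclei=25, per_nucleus_her2=("fixed", 2), per_nucleus_cep17=("fixed", 2)
    ),
    "amplified": SyntheticSpec(
        n_nuclei=30, per_nucleus_her2=("fixed", 6), per_nucleus_cep17=("fixed", 2),
        image_size=(704, 704),
    ),
    "equivocal": SyntheticSpec(
        n_nuclei=45, per_nucleus_her2=("fixed", 4), per_nucleus_cep17=("fixed", 2),
        image_size=(832, 832),
    ),
    "high-positivity": SyntheticSpec(
        n_nuclei=25, per_nucleus_her2=("fixed", 8), per_nucleus_cep17=("fixed", 1),
        image_size=(704, 704),
    ),
}


def preset(name: str, seed: int = 0, **overrides) -> SyntheticSpec:
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return replace(PRESETS[name], seed=seed, **overrides)
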