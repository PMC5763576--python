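"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates the study conditions of a long-term MSC culture
experiment: per-passage cell-area distributions are right-skewed
(lognormal, moment-matched to the published per-passage means/SDs),
fields contain border-touching cells, touching cell pairs, binucleate
objects and sub-gate debris, TRF gel lanes have an analytically known
OD-weighted mean fragment length, and marker panels are drawn from a
target correlation structure.

Everything is driven by explicit integer seeds: identical seeds yield
bit-identical images, tables and profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt, gaussian_filter, gaussian_filter1d
from skimage.draw import disk as draw_disk
from skimage.draw import polygon as draw_polygon

from .imaging import FieldImage
from .trf import LadderCalibration, LaneProfile, calibrate_ladder

__all__ = [
    "PassageSizeModel",
    "FieldSpec",
    "GroundTruth",
    "TRFSimSpec",
    "MarkerSimSpec",
    "PlacementError",
    "TABLE2_SIZE_MODELS",
    "MARKER_COLUMNS",
    "MARKER_CORRELATION",
    "DEFAULT_LADDER_RUNGS",
    "default_ladder",
    "lognormal_params",
    "sample_areas",
    "generate_field",
    "generate_passage_dataset",
    "generate_trf_lane",
    "generate_marker_panel",
]


class PlacementError(RuntimeError):
    """Raised when cells cannot be placed without exceeding the overlap budget."""


@dataclass(frozen=True)
class PassageSizeModel:
    """Lognormal cell-area model for one passage group.

    ``mean_area``/``sd_area`` are in μm² and are matched by moments
    (the generated distribution has exactly this mean and SD).  ``pd_mean``
    and ``pd_sd`` give the population-doubling number attached to the
    passage when building donor×passage datasets.
    """

    passage_label: str
    mean_area: float
    sd_area: float
    skew_family: str = "lognormal"
    pd_mean: float = 0.0
    pd_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.mean_area <= 0 or self.sd_area <= 0:
            raise ValueError("mean_area and sd_area must be positive")
        if self.skew_family != "lognormal":
            raise ValueError(f"unsupported skew_family {self.skew_family!r}")


#: Published per-passage means/SDs of cell area (μm²) and PD numbers for the
#: four imaged passages of the long-term cultures; these defaults define the
#: conditions every end-to-end recovery run is seeded with.
TABLE2_SIZE_MODELS = [
    PassageSizeModel("p1", 1827.0, 329.0, pd_mean=19.3, pd_sd=1.5),
    PassageSizeModel("p3", 2352.0, 386.0, pd_mean=28.3, pd_sd=2.1),
    PassageSizeModel("p5", 4198.0, 1628.0, pd_mean=33.5, pd_sd=4.7),
    PassageSizeModel("pSEN", 8744.0, 2494.0, pd_mean=36.6, pd_sd=7.1),
]


@dataclass(frozen=True)
class FieldSpec:
    """Layout of one synthetic two-channel field."""

    field_size: tuple[int, int] = (512, 512)
    pixel_size: float = 0.65  # μm/px, typical 10x high-content setup
    n_cells: int = 12
    fraction_border: float = 0.0
    fraction_touching: float = 0.0
    fraction_binucleate: float = 0.0
    fraction_debris: float = 0.0
    noise_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (
            self.fraction_border,
            self.fraction_touching,
            self.fraction_binucleate,
            self.fraction_debris,
        )
        if any(f < 0 or f > 1 for f in fracs):
            raise ValueError("all fractions must lie in [0, 1]")
        if sum(fracs) > 1 + 1e-12:
            raise ValueError("fractions must sum to at most 1")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.n_cells < 0:
            raise ValueError("n_cells must be nonnegative")


@dataclass
class GroundTruth:
    """Per-object truth for one synthetic field."""

    label_mask: np.ndarray  # int32, 0 = background
    table: pd.DataFrame  # object_id, true_area, n_nuclei, touches_border, is_debris, kind

    def __len__(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# area sampling

def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the lognormal with the given arithmetic mean and SD."""
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def sample_areas(model: PassageSizeModel, n: int, rng: np.random.Generator) -> np.ndarray:
    mu, sigma = lognormal_params(model.mean_area, model.sd_area)
    return rng.lognormal(mu, sigma, size=n)


# ---------------------------------------------------------------------------
# field generation

_NUCLEUS_AREA_UM2 = 170.0  # adult stromal cell nucleus, ~15 μm across
_CELL_BASE_INTENSITY = (380.0, 650.0)
_BACKGROUND = 100.0
_EDGE_FALLOFF = 0.65  # cytoplasm edge intensity as a fraction of the cell center


def _star_polygon(
    area_px: float, rng: np.random.Generator, n_vertices: int = 16, roughness: float = 0.35
) -> np.ndarray:
    """Closed star-convex polygon (N×2, row/col) with ~the requested pixel area.

    Radius perturbation of a circle, smoothed along the contour; a fixture
    shape choice, not biology.
    """
    angles = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
    bumps = rng.normal(0.0, roughness, n_vertices)
    bumps = gaussian_filter1d(bumps, 1.5, mode="wrap")
    radii = 1.0 + np.clip(bumps, -0.55, 0.8)
    pts = np.column_stack([radii * np.sin(angles), radii * np.cos(angles)])
    # shoelace area of the unit-ish polygon, then rescale to the target
    x, y = pts[:, 1], pts[:, 0]
    shoelace = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    return pts * np.sqrt(area_px / shoelace)


def _rasterize(poly: np.ndarray, center: tuple[float, float], shape: tuple[int, int]) -> np.ndarray:
    rr, cc = draw_polygon(poly[:, 0] + center[0], poly[:, 1] + center[1], shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def _place(
    occupied: np.ndarray,
    poly: np.ndarray,
    rng: np.random.Generator,
    *,
    border: bool,
    margin: int = 2,
    attempts: int = 100,
) -> np.ndarray | None:
    """Find a non-overlapping placement; None after the attempt budget."""
    h, w = occupied.shape
    r_max = float(np.abs(poly).max())
    for _ in range(attempts):
        if border:
            edge = rng.integers(4)
            along = rng.uniform(r_max, (w if edge < 2 else h) - r_max)
            off = rng.uniform(-0.3 * r_max, 0.3 * r_max)
            if edge == 0:
                center = (off, along)
            elif edge == 1:
                center = (h - 1 + off, along)
            elif edge == 2:
                center = (along, off)
            else:
                center = (along, w - 1 + off)
        else:
            lo, hi_r, hi_c = r_max + margin, h - r_max - margin, w - r_max - margin
            if hi_r <= lo or hi_c <= lo:
                return None
            center = (rng.uniform(lo, hi_r), rng.uniform(lo, hi_c))
        mask = _rasterize(poly, center, occupied.shape)
        if not mask.any():
            continue
        grown = np.zeros_like(mask)
        rs, cs = np.nonzero(mask)
        r0, r1 = max(rs.min() - margin, 0), min(rs.max() + margin + 1, h)
        c0, c1 = max(cs.min() - margin, 0), min(cs.max() + margin + 1, w)
        grown[r0:r1, c0:c1] = distance_transform_edt(~mask[r0:r1, c0:c1]) <= margin
        if not (grown & occupied).any():
            if border and not (
                mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any()
            ):
                continue
            return mask
    return None


def _nucleus_sites(mask: np.ndarray, n: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    """n well-separated interior points of the mask (nucleus centers)."""
    edt = distance_transform_edt(mask)
    interior = np.argwhere(edt > max(2.0, 0.25 * edt.max()))
    if len(interior) == 0:
        interior = np.argwhere(mask)
    if n == 1:
        r, c = np.unravel_index(np.argmax(edt), edt.shape)
        jit = rng.integers(-2, 3, size=2)
        site = (
            int(np.clip(r + jit[0], 0, mask.shape[0] - 1)),
            int(np.clip(c + jit[1], 0, mask.shape[1] - 1)),
        )
        if not mask[site]:
            site = (int(r), int(c))
        return [site]
    # two nuclei: pick the most separated interior pair from a random subset
    idx = rng.choice(len(interior), size=min(len(interior), 64), replace=False)
    pts = interior[idx]
    d = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    i, j = np.unravel_index(np.argmax(d), d.shape)
    return [tuple(pts[i]), tuple(pts[j])]


def generate_field(
    spec: FieldSpec, size_model: PassageSizeModel
) -> tuple[FieldImage, GroundTruth]:
    """One synthetic two-channel field plus per-object ground truth.

    Object mix follows the spec fractions: border-crossing cells,
    touching pairs (adjacent masks, separate labels), binucleate cells
    and anucleate sub-gate debris; the remainder are clean singletons.
    Raises :class:`PlacementError` when the field is overcrowded.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.field_size
    ps = spec.pixel_size
    n = spec.n_cells

    n_border = int(round(spec.fraction_border * n))
    n_touch_pairs = int(round(spec.fraction_touching * n)) // 2
    n_binuc = int(round(spec.fraction_binucleate * n))
    n_debris = int(round(spec.fraction_debris * n))
    n_plain = n - n_border - 2 * n_touch_pairs - n_binuc - n_debris

    kinds: list[str] = (
        ["plain"] * n_plain
        + ["border"] * n_border
        + ["pair"] * n_touch_pairs
        + ["binucleate"] * n_binuc
        + ["debris"] * n_debris
    )

    label_mask = np.zeros((h, w), dtype=np.int32)
    occupied = np.zeros((h, w), dtype=bool)
    rows = []
    nuclei_sites: list[tuple[tuple[int, int], float]] = []  # (site, radius_px)
    next_label = 1

    def add_object(mask: np.ndarray, kind: str, n_nuclei: int) -> None:
        nonlocal next_label
        label_mask[mask] = next_label
        occupied[mask] = True
        for site in _nucleus_sites(mask, n_nuclei, rng) if n_nuclei else []:
            nuc_r = np.sqrt(rng.normal(_NUCLEUS_AREA_UM2, 15.0) / np.pi) / ps
            nuclei_sites.append((site, max(nuc_r, 3.0)))
        rows.append(
            {
                "object_id": next_label,
                "kind": kind,
                "n_nuclei": n_nuclei,
                "is_debris": kind == "debris",
            }
        )
        next_label += 1

    for kind in kinds:
        if kind == "debris":
            area_px = rng.uniform(80.0, 600.0) / ps**2
            poly = _star_polygon(area_px, rng, n_vertices=10, roughness=0.5)
            mask = _place(occupied, poly, rng, border=False)
            if mask is None:
                raise PlacementError("could not place debris within the attempt budget")
            add_object(mask, "debris", 0)
            continue

        if kind == "pair":
            # both cells of a touching pair are sited together; if no
            # adjacent partner spot exists, the anchor is re-placed too
            placed_pair = False
            for _ in range(20):
                area_px = float(sample_areas(size_model, 1, rng)[0]) / ps**2
                poly = _star_polygon(area_px, rng)
                mask = _place(occupied, poly, rng, border=False)
                if mask is None:
                    break
                area2_px = float(sample_areas(size_model, 1, rng)[0]) / ps**2
                poly2 = _star_polygon(area2_px, rng)
                base = np.argwhere(mask).mean(axis=0)
                r1, r2 = np.sqrt(area_px / np.pi), np.sqrt(area2_px / np.pi)
                gap = distance_transform_edt(~mask)
                for _ in range(100):
                    theta = rng.uniform(0, 2 * np.pi)
                    dist = rng.uniform(0.92, 1.04) * (r1 + r2)
                    center = (base[0] + dist * np.sin(theta), base[1] + dist * np.cos(theta))
                    cand = _rasterize(poly2, center, (h, w))
                    cand &= ~mask  # the anchor cell keeps its pixels
                    if not cand.any():
                        continue
                    on_border = (
                        cand[0, :].any()
                        or cand[-1, :].any()
                        or cand[:, 0].any()
                        or cand[:, -1].any()
                    )
                    if (
                        (gap[cand] <= 1.5).any()
                        and not (cand & occupied).any()
                        and not on_border
                        and cand.sum() >= 0.7 * area2_px
                    ):
                        add_object(mask, "pair", 1)
                        add_object(cand, "pair", 1)
                        placed_pair = True
                        break
                if placed_pair:
                    break
            if not placed_pair:
                raise PlacementError(
                    f"could not place a touching pair within the attempt budget "
                    f"(n_cells={n} on a {h}x{w} field)"
                )
            continue

        area_px = float(sample_areas(size_model, 1, rng)[0]) / ps**2
        poly = _star_polygon(area_px, rng)
        mask = _place(occupied, poly, rng, border=(kind == "border"))
        if mask is None:
            raise PlacementError(
                f"could not place a {kind} cell within the attempt budget "
                f"(n_cells={n} on a {h}x{w} field)"
            )
        add_object(mask, kind, 2 if kind == "binucleate" else 1)

    # ---- truth table geometry ----
    for row in rows:
        m = label_mask == row["object_id"]
        row["true_area"] = float(m.sum()) * ps**2
        row["touches_border"] = bool(
            m[0, :].any() or m[-1, :].any() or m[:, 0].any() or m[:, -1].any()
        )
    table = pd.DataFrame(
        rows,
        columns=["object_id", "kind", "true_area", "n_nuclei", "touches_border", "is_debris"],
    )

    # ---- render channels ----
    cyto = np.full((h, w), _BACKGROUND, dtype=float)
    if label_mask.any():
        for row in rows:
            # each cell's stain falls off toward its own membrane, so a
            # dim seam exists wherever two distinct cells touch
            m = label_mask == row["object_id"]
            local = distance_transform_edt(m)
            base = rng.uniform(*_CELL_BASE_INTENSITY)
            peak = max(local.max(), 1.0)
            cyto[m] = base * (_EDGE_FALLOFF + (1 - _EDGE_FALLOFF) * local[m] / peak)
    nuc = np.full((h, w), _BACKGROUND, dtype=float)
    for (r, c), nr in nuclei_sites:
        rr, cc = draw_disk((r, c), nr, shape=(h, w))
        nuc[rr, cc] = 900.0
    nuc = gaussian_filter(nuc, 1.0)
    if spec.noise_sd > 0:
        cyto = cyto + rng.normal(0.0, spec.noise_sd, (h, w))
        nuc = nuc + rng.normal(0.0, spec.noise_sd, (h, w))

    field_img = FieldImage(
        nucleus_channel=nuc.astype(np.float32),
        cytoplasm_channel=cyto.astype(np.float32),
        pixel_size=ps,
        field_id=f"synthetic-{spec.seed}",
    )
    return field_img, GroundTruth(label_mask=label_mask, table=table)


# ---------------------------------------------------------------------------
# donor x passage datasets (area-only fast path)

_SHAPE_RATIO_PARAMS = {
    # passage-independent shape marginals for the fast (no-imaging) path;
    # chosen to respect every CellRecord invariant by construction
    "perimeter_area_ratio": (np.log(1.8), 0.25),  # lognormal, >= 1 after +offset below
    "length_width_ratio": (np.log(0.8), 0.5),  # 1 + lognormal
    "convex_hull_area_ratio": (np.log(0.15), 0.5),  # 1 + lognormal
}


def generate_passage_dataset(
    models: list[PassageSizeModel],
    n_donors: int,
    cells_per_group: int,
    seed: int = 0,
    donor_scale_sd: float = 0.06,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Donor×passage cell table without imaging (area-only mode).

    Each donor carries a multiplicative size factor (SD ``donor_scale_sd``)
    so donor effects are present, as in real cultures.  Size descriptors
    are derived from the sampled area and sampled shape ratios so that
    every record satisfies the CellRecord invariants; shape marginals do
    not depend on passage (size, not shape, carries the aging signal).

    Returns ``(records, pd_table)`` where ``pd_table`` has one PD value
    per donor×passage group.
    """
    if not models:
        raise ValueError("empty model list")
    if n_donors < 1 or cells_per_group < 1:
        raise ValueError("n_donors and cells_per_group must be >= 1")
    rng = np.random.default_rng(seed)
    donor_ids = [f"MSC-{i + 1}" for i in range(n_donors)]
    donor_factor = dict(zip(donor_ids, rng.normal(1.0, donor_scale_sd, n_donors)))

    rec_parts = []
    pd_rows = []
    for donor in donor_ids:
        for model in models:
            n = cells_per_group
            area = sample_areas(model, n, rng) * donor_factor[donor]
            mu, sg = _SHAPE_RATIO_PARAMS["perimeter_area_ratio"]
            circ = 1.05 + rng.lognormal(mu - np.log(1.8) + np.log(0.75), sg, n)
            mu, sg = _SHAPE_RATIO_PARAMS["length_width_ratio"]
            lwr = 1.0 + rng.lognormal(mu, sg, n)
            bfr = rng.beta(8.0, 4.5, n)  # in (0, 1), mode ~0.67
            mu, sg = _SHAPE_RATIO_PARAMS["convex_hull_area_ratio"]
            char = 1.0 + rng.lognormal(mu, sg, n)
            chpr = 1.0 / (1.0 + rng.lognormal(np.log(0.08), 0.6, n))
            length = np.sqrt(area * lwr / bfr)
            width = np.sqrt(area / (lwr * bfr))
            perimeter = np.sqrt(circ * 4 * np.pi * area)
            rec_parts.append(
                pd.DataFrame(
                    {
                        "donor": donor,
                        "passage": model.passage_label,
                        "length": length,
                        "width": width,
                        "area": area,
                        "perimeter": perimeter,
                        "perimeter_area_ratio": circ,
                        "length_width_ratio": lwr,
                        "boxed_frame_ratio": bfr,
                        "convex_hull_area_ratio": char,
                        "convex_hull_perimeter_ratio": chpr,
                    }
                )
            )
            pd_rows.append(
                {
                    "donor": donor,
                    "passage": model.passage_label,
                    "pd": rng.normal(model.pd_mean, model.pd_sd) if model.pd_sd else model.pd_mean,
                }
            )
    records = pd.concat(rec_parts, ignore_index=True)
    records.insert(0, "cell_id", [f"cell{i:06d}" for i in range(len(records))])
    return records, pd.DataFrame(pd_rows)


# ---------------------------------------------------------------------------
# TRF gel lanes

#: Migration ladder emulating a telomere-length assay sizing ladder; rung
#: positions are exactly log-linear in fragment length, the standard gel
#: migration behaviour.
DEFAULT_LADDER_RUNGS = [
    (10.0 + 90.0 * (np.log10(21.2) - np.log10(L)) / (np.log10(21.2) - np.log10(1.9)), L)
    for L in (21.2, 8.6, 7.4, 6.1, 5.0, 4.2, 3.6, 2.7, 1.9)
]


def default_ladder() -> LadderCalibration:
    return calibrate_ladder(DEFAULT_LADDER_RUNGS)


@dataclass(frozen=True)
class TRFSimSpec:
    """A lane as a mixture of telomere fragment bands.

    ``smear_sd`` is the band spread in kbp; at ``smear_sd == 0`` (and zero
    baseline) the lane's OD-weighted mean length equals the analytic
    mixture mean Σ(wᵢLᵢ)/Σ(wᵢ) exactly.
    """

    fragment_lengths: tuple[float, ...]
    fragment_weights: tuple[float, ...]
    smear_sd: float = 0.3
    baseline: float = 0.0
    seed: int = 0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if len(self.fragment_lengths) != len(self.fragment_weights):
            raise ValueError("lengths and weights must have equal size")
        if not self.fragment_lengths:
            raise ValueError("at least one fragment required")
        if any(length <= 0 for length in self.fragment_lengths):
            raise ValueError("all fragment lengths must be positive")
        if any(w < 0 for w in self.fragment_weights) or sum(self.fragment_weights) <= 0:
            raise ValueError("weights must be nonnegative with positive sum")

    @property
    def analytic_mean_kbp(self) -> float:
        w = np.asarray(self.fragment_weights, dtype=float)
        L = np.asarray(self.fragment_lengths, dtype=float)
        return float(np.sum(w * L) / np.sum(w))


def generate_trf_lane(
    spec: TRFSimSpec,
    ladder: LadderCalibration | None = None,
    n_samples: int = 800,
    lane_id: str = "lane",
) -> LaneProfile:
    """Densitometry profile of a simulated lane on the ladder's position axis.

    Bands are Gaussian in *position* with a width equivalent to
    ``smear_sd`` kbp at each band's location, so the OD-weighted mean on
    the profile converges to the analytic mixture mean as the smear
    narrows.
    """
    ladder = ladder or default_ladder()
    lo, hi = ladder.position_span
    for L in spec.fragment_lengths:
        if not (ladder.length_span[0] <= L <= ladder.length_span[1]):
            raise ValueError(
                f"fragment {L} kbp outside ladder range {ladder.length_span}"
            )
    positions = np.linspace(lo, hi, n_samples)
    od = np.full(n_samples, float(spec.baseline))
    dx = positions[1] - positions[0]
    for L, wgt in zip(spec.fragment_lengths, spec.fragment_weights):
        if wgt == 0:
            continue
        p0 = ladder.length_to_position(L)
        if spec.smear_sd <= 0:
            # snap the nearest grid sample onto the exact band position so
            # the discrete profile carries the band's true length
            idx = int(round((p0 - lo) / dx))
            positions[idx] = p0
            od[idx] += wgt
            continue
        # convert the kbp band width to position units at this band
        eps = min(spec.smear_sd, 0.05 * L)
        slope = abs(ladder.length_to_position(L + eps) - ladder.length_to_position(L - eps)) / (
            2 * eps
        )
        sd_pos = max(spec.smear_sd * slope, dx)
        od += wgt * np.exp(-0.5 * ((positions - p0) / sd_pos) ** 2) / (sd_pos * np.sqrt(2 * np.pi))
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        od = np.clip(od + rng.normal(0.0, spec.noise_sd, n_samples), 0.0, None)
    return LaneProfile(positions=positions, od=od, lane_id=lane_id)


# ---------------------------------------------------------------------------
# marker panels

MARKER_COLUMNS = [
    "mean_cell_area",
    "pd_per_day",
    "p16",
    "p21",
    "sa_b_gal",
    "mean_telomere_length",
]

#: Published pairwise Pearson correlations between mean cell area and the
#: aging markers (rows/columns ordered as MARKER_COLUMNS); verified positive
#: definite, so it is usable directly as a Gaussian copula correlation.
MARKER_CORRELATION = np.array(
    [
        [1.00, -0.74, 0.50, 0.52, 0.70, -0.71],
        [-0.74, 1.00, -0.59, -0.67, -0.80, 0.89],
        [0.50, -0.59, 1.00, 0.52, 0.66, -0.36],
        [0.52, -0.67, 0.52, 1.00, 0.23, -0.63],
        [0.70, -0.80, 0.66, 0.23, 1.00, -0.65],
        [-0.71, 0.89, -0.36, -0.63, -0.65, 1.00],
    ]
)

#: (location, scale) per marker giving realistic units: μm², PD/day,
#: fold-expression, fold-expression, RFU, kbp.  Affine scaling does not
#: change Pearson correlations.
MARKER_SCALES = {
    "mean_cell_area": (4280.0, 2800.0),
    "pd_per_day": (0.62, 0.25),
    "p16": (12.0, 11.0),
    "p21": (1.6, 0.5),
    "sa_b_gal": (3200.0, 1600.0),
    "mean_telomere_length": (7.5, 0.7),
}


@dataclass(frozen=True)
class MarkerSimSpec:
    """Gaussian-copula marker panel specification."""

    target_correlation: np.ndarray = field(
        default_factory=lambda: MARKER_CORRELATION.copy()
    )
    n_groups: int = 12
    seed: int = 0
    repair_non_psd: bool = True

    def __post_init__(self) -> None:
        C = np.asarray(self.target_correlation, dtype=float)
        if C.ndim != 2 or C.shape[0] != C.shape[1] or C.shape[0] != len(MARKER_COLUMNS):
            raise ValueError(f"target_correlation must be {len(MARKER_COLUMNS)}x{len(MARKER_COLUMNS)}")
        if not np.allclose(C, C.T, atol=1e-10):
            raise ValueError("target_correlation must be symmetric")
        if not np.allclose(np.diag(C), 1.0, atol=1e-10):
            raise ValueError("target_correlation must have a unit diagonal")
        if self.n_groups < 2:
            raise ValueError("n_groups must be >= 2")


def _nearest_psd_correlation(C: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eigh(C)
    w = np.clip(w, 1e-8, None)
    R = V @ np.diag(w) @ V.T
    d = np.sqrt(np.diag(R))
    return R / np.outer(d, d)


def generate_marker_panel(spec: MarkerSimSpec) -> pd.DataFrame:
    """Marker table (one row per donor×passage group) with the target
    correlation structure; sample correlations converge to the target as
    ``n_groups`` grows."""
    C = np.asarray(spec.target_correlation, dtype=float)
    eigmin = float(np.linalg.eigvalsh(C).min())
    if eigmin < -1e-10:
        if not spec.repair_non_psd:
            raise ValueError(f"target_correlation is not PSD (min eigenvalue {eigmin:.3g})")
        warnings.warn(
            f"target_correlation not PSD (min eigenvalue {eigmin:.3g}); "
            "repaired to the nearest correlation matrix",
            stacklevel=2,
        )
        C = _nearest_psd_correlation(C)
    rng = np.random.default_rng(spec.seed)
    w, V = np.linalg.eigh(C)
    root = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    z = rng.standard_normal((spec.n_groups, C.shape[0])) @ root.T
    data = {}
    for j, col in enumerate(MARKER_COLUMNS):
        loc, scale = MARKER_SCALES[col]
        data[col] = loc + scale * z[:, j]
    out = pd.DataFrame(data)
    out.insert(0, "group", [f"g{i:03d}" for i in range(spec.n_groups)])
    return out
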