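"""Synthetic muscle sections and qPCR plates with known ground truth.

The image generator emulates the data regime of a transverse TA muscle
cryosection stained for laminin (fiber boundaries) and the four MyHC
isotypes: a Lloyd-relaxed Voronoi mosaic of convex fibers, a boundary
ridge with configurable contiguous gaps (the failure mode the
shrink/expand gap repair must fix), per-fiber MyHC compositions drawn
from a fiber-type mixture with correlated jitter, peripheral or central
DAPI nuclei, a GFP transduction channel, an activity-probe channel with a
multiplicative knockdown effect in GFP-positive fibers, and a collagen
ridge along the extracellular matrix.

The qPCR generator emulates paired-cohort Ct tables: per-sample input
offsets shared by all genes of a sample (so housekeeping normalization
cancels them), replicate noise, knockdown fold changes, and
distal/proximal primer sets whose Ct difference encodes distal
polyadenylation-site utilization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.draw import disk as draw_disk
from skimage.filters import gaussian
from skimage.morphology import dilation, disk
from skimage.segmentation import find_boundaries

from . import section as sec
from .design import CohortDesign, PBS, SCRAM, SHPAB, generate_cohort  # noqa: F401 (re-export)
from .exceptions import ConfigurationError, PlacementError
from .section import FiberLabelMap, MultiChannelSection, MYHC_CHANNELS, SampleInfo

__all__ = [
    "TypeProfile",
    "SectionSpec",
    "GroundTruth",
    "GeneSpec",
    "QpcrSpec",
    "condition_profile",
    "generate_section",
    "generate_qpcr",
    "generate_cohort",
    "sample_fiber_compositions",
]


# ---------------------------------------------------------------------------
# Fiber-type intensity model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TypeProfile:
    """Mixture model for per-fiber MyHC compositions.

    Each fiber draws a type from ``mixing`` and a 4-vector composition
    (weights over MyHC-2b, -2x, -2a, -1) = type mean + correlated Gaussian
    jitter, clipped at zero. Co-expression of neighbouring isotypes and the
    2b/2x anticorrelation that the co-expression statistics analyse come
    from the overlapping type means and the jitter correlation.
    """

    type_names: tuple[str, ...]
    compositions: np.ndarray  # (n_types, 4)
    mixing: np.ndarray  # (n_types,)
    jitter_sd: np.ndarray  # (4,)
    jitter_corr: np.ndarray  # (4, 4)

    def __post_init__(self) -> None:
        comp = np.asarray(self.compositions, dtype=float)
        mix = np.asarray(self.mixing, dtype=float)
        sd = np.asarray(self.jitter_sd, dtype=float)
        corr = np.asarray(self.jitter_corr, dtype=float)
        object.__setattr__(self, "compositions", comp)
        object.__setattr__(self, "mixing", mix)
        object.__setattr__(self, "jitter_sd", sd)
        object.__setattr__(self, "jitter_corr", corr)
        if comp.shape != (len(self.type_names), 4):
            raise ValueError("compositions must be (n_types, 4)")
        if (comp < 0).any() or (comp.sum(axis=1) <= 0).any():
            raise ValueError("type compositions must be non-negative with positive sums")
        if mix.shape != (len(self.type_names),) or (mix < 0).any():
            raise ValueError("mixing fractions must be non-negative")
        if not math.isclose(mix.sum(), 1.0, rel_tol=1e-9):
            raise ValueError("mixing fractions must sum to 1")
        if sd.shape != (4,) or (sd < 0).any():
            raise ValueError("jitter_sd must be 4 non-negative values")
        if corr.shape != (4, 4) or not np.allclose(corr, corr.T):
            raise ValueError("jitter_corr must be a symmetric 4x4 matrix")
        # require (near-)positive-semidefiniteness up front
        if np.linalg.eigvalsh(corr).min() < -1e-9:
            raise ValueError("jitter_corr must be positive semidefinite")

    @property
    def covariance(self) -> np.ndarray:
        d = np.diag(self.jitter_sd)
        return d @ self.jitter_corr @ d


def _corr(pairs: Mapping[tuple[int, int], float]) -> np.ndarray:
    m = np.eye(4)
    for (i, j), r in pairs.items():
        m[i, j] = m[j, i] = r
    return m


#: Control (Scram) muscle: fast TA dominated by 2b fibers, strong
#: anticorrelation between 2b and the slower isotypes.
SCRAM_PROFILE = TypeProfile(
    type_names=("IIb", "IIx", "IIa", "I"),
    compositions=np.array(
        [
            [1.00, 0.28, 0.04, 0.01],
            [0.35, 1.00, 0.15, 0.03],
            [0.08, 0.35, 1.00, 0.12],
            [0.03, 0.08, 0.30, 1.00],
        ]
    ),
    mixing=np.array([0.56, 0.36, 0.06, 0.02]),
    jitter_sd=np.array([0.16, 0.16, 0.08, 0.05]),
    jitter_corr=_corr({(0, 1): -0.75, (1, 2): 0.25, (2, 3): 0.20}),
)

#: Knockdown (shPab) muscle: 2b mixing fraction reduced, 2x increased,
#: compositions pulled toward co-expression and jitter decorrelated —
#: yielding the fast-to-slow fiber-type transition and the weakened
#: 2b co-expression correlations.
SHPAB_PROFILE = TypeProfile(
    type_names=("IIb", "IIx", "IIa", "I"),
    compositions=np.array(
        [
            [0.72, 0.58, 0.08, 0.02],
            [0.50, 0.95, 0.22, 0.04],
            [0.12, 0.42, 0.90, 0.14],
            [0.04, 0.10, 0.32, 0.90],
        ]
    ),
    mixing=np.array([0.33, 0.51, 0.11, 0.05]),
    jitter_sd=np.array([0.20, 0.20, 0.10, 0.06]),
    jitter_corr=_corr({(0, 1): -0.25, (1, 2): 0.10, (2, 3): 0.10}),
)


def condition_profile(condition: str) -> TypeProfile:
    """Default fiber-type profile for a condition (PBS behaves like Scram)."""
    if condition == SHPAB:
        return SHPAB_PROFILE
    return SCRAM_PROFILE


def sample_fiber_compositions(
    profile: TypeProfile, n_fibers: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-fiber MyHC compositions from a type profile.

    Returns
    -------
    types : (n,) integer type indices
    compositions : (n, 4) non-negative weights (type mean + correlated
        Gaussian jitter, clipped at 0)
    """
    types = rng.choice(len(profile.type_names), size=n_fibers, p=profile.mixing)
    jitter = rng.multivariate_normal(
        np.zeros(4), profile.covariance, size=n_fibers, method="cholesky"
    )
    comp = np.clip(profile.compositions[types] + jitter, 0.0, None)
    return types, comp


# ---------------------------------------------------------------------------
# Section generator
# ---------------------------------------------------------------------------

@dataclass
class SectionSpec:
    """Parameters of one synthetic muscle section.

    Intensity units are arbitrary fluorescence counts; lengths are pixels
    unless suffixed ``_um``. ``background_level`` may be a scalar applied
    to every channel or a per-channel mapping.
    """

    n_fibers: int = 200
    field_size: int = 512
    mean_fiber_radius: float = 16.0
    boundary_width: int = 3
    gap_fraction: float = 0.0
    gap_run_px: float = 5.0
    type_profile: TypeProfile = field(default_factory=lambda: SCRAM_PROFILE)
    intensity_noise_sd: float = 5.0
    background_level: float | Mapping[str, float] = 40.0
    central_nucleation_fraction: float = 0.05
    gfp_positive_fraction: float = 0.7
    probe_effect: float = 1.0
    collagen_scale: float = 0.3
    seed: int = 0
    # secondary knobs
    pixel_size_um: float = 1.0
    myhc_amplitude: float = 1000.0
    channel_gain: Mapping[str, float] = field(
        default_factory=lambda: {
            sec.MYHC_2B: 1.0,
            sec.MYHC_2X: 1.5,
            sec.MYHC_2A: 0.8,
            sec.MYHC_1: 1.2,
        }
    )
    laminin_amplitude: float = 1000.0
    laminin_blur_sigma: float = 0.5
    nucleus_radius_px: int = 3
    dapi_amplitude: float = 600.0
    gfp_amplitude: float = 800.0
    probe_base: float = 400.0
    sample: SampleInfo = field(default_factory=SampleInfo)

    def background(self, channel: str) -> float:
        if isinstance(self.background_level, Mapping):
            return float(self.background_level.get(channel, 0.0))
        return float(self.background_level)

    def validate(self) -> None:
        if self.n_fibers < 1:
            raise ValueError("n_fibers must be >= 1")
        if not 0.0 <= self.gap_fraction < 1.0:
            raise ValueError("gap_fraction must lie in [0, 1)")
        if not 0.0 <= self.central_nucleation_fraction <= 1.0:
            raise ValueError("central_nucleation_fraction must lie in [0, 1]")
        if not 0.0 <= self.gfp_positive_fraction <= 1.0:
            raise ValueError("gfp_positive_fraction must lie in [0, 1]")
        if self.intensity_noise_sd < 0:
            raise ValueError("intensity_noise_sd must be >= 0")
        if self.probe_effect < 0:
            raise ValueError("probe_effect must be >= 0")
        # Can the requested fibers fit at the requested radius?
        packing = self.n_fibers * math.pi * self.mean_fiber_radius**2
        if packing > self.field_size**2:
            raise PlacementError(
                f"cannot place {self.n_fibers} fibers of mean radius "
                f"{self.mean_fiber_radius} px in a {self.field_size} px field"
            )


@dataclass
class GroundTruth:
    """What the generator actually drew, for oracle-based testing.

    ``true_fiber_table`` holds one row per fiber with its pixel area and
    the noiseless mean intensity of every channel over its pixels (columns
    ``mean_<channel>``), the drawn type, composition weights and GFP state.
    """

    true_label_map: FiberLabelMap
    true_fiber_table: pd.DataFrame
    true_parameters: dict
    true_nucleus_map: np.ndarray | None = None

    @property
    def n_nuclei(self) -> int:
        if self.true_nucleus_map is None:
            return 0
        return int(self.true_nucleus_map.max())

    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.true_label_map.save(directory / "true_labels.tif")
        self.true_fiber_table.to_csv(directory / "true_fibers.csv", index=False)
        if self.true_nucleus_map is not None:
            import tifffile

            tifffile.imwrite(
                directory / "true_nuclei.tif", self.true_nucleus_map.astype(np.uint16)
            )
        import json

        (directory / "true_parameters.json").write_text(
            json.dumps(self.true_parameters, indent=2, sort_keys=True, default=str)
        )
        return directory


def _place_seeds(spec: SectionSpec, rng: np.random.Generator) -> np.ndarray:
    """Dart-throwing placement with a minimum spacing of one mean radius."""
    min_dist = spec.mean_fiber_radius
    margin = 2.0
    low, high = margin, spec.field_size - margin
    points: list[np.ndarray] = []
    attempts = 0
    max_attempts = 500 * spec.n_fibers
    while len(points) < spec.n_fibers:
        if attempts >= max_attempts:
            raise PlacementError(
                f"placed only {len(points)}/{spec.n_fibers} fiber seeds after "
                f"{max_attempts} attempts; field too small for mean radius "
                f"{spec.mean_fiber_radius} px"
            )
        cand = rng.uniform(low, high, size=2)
        attempts += 1
        if all(np.hypot(*(cand - p)) >= min_dist for p in points):
            points.append(cand)
    return np.asarray(points)


def _tessellate(spec: SectionSpec, rng: np.random.Generator) -> np.ndarray:
    """Lloyd-relaxed (2 iterations) Voronoi assignment of pixels to seeds."""
    seeds = _place_seeds(spec, rng)
    n = spec.field_size
    yy, xx = np.indices((n, n))
    pixels = np.column_stack([yy.ravel(), xx.ravel()]).astype(float)
    assign = None
    for _ in range(2):  # Lloyd relaxation for convex, size-regular cells
        _, assign = cKDTree(seeds).query(pixels)
        for axis in range(2):
            sums = np.bincount(assign, weights=pixels[:, axis], minlength=len(seeds))
            counts = np.bincount(assign, minlength=len(seeds))
            nonzero = counts > 0
            seeds[nonzero, axis] = sums[nonzero] / counts[nonzero]
    _, assign = cKDTree(seeds).query(pixels)
    return (assign + 1).reshape(n, n).astype(np.int32)


def _delete_gaps(
    boundary: np.ndarray, gap_fraction: float, gap_run_px: float, rng: np.random.Generator
) -> np.ndarray:
    """Remove ~gap_fraction of boundary pixels in contiguous runs.

    Each run is a disk of diameter ``gap_run_px`` punched out of the
    boundary. New run centres are excluded from a guard zone around
    existing runs so adjacent runs cannot coalesce into gaps wider than
    the configured length.
    """
    if gap_fraction <= 0:
        return boundary
    coords = np.argwhere(boundary)
    n_total = len(coords)
    target = int(round(gap_fraction * n_total))
    if target == 0:
        return boundary
    tree = cKDTree(coords)
    alive = np.ones(n_total, dtype=bool)
    eligible = np.ones(n_total, dtype=bool)
    removed = 0
    out = boundary.copy()
    while removed < target:
        candidates = np.flatnonzero(eligible)
        if candidates.size == 0:
            break
        centre = candidates[rng.integers(candidates.size)]
        for h in tree.query_ball_point(coords[centre], r=1.5 * gap_run_px):
            eligible[h] = False
        hit = [h for h in tree.query_ball_point(coords[centre], r=gap_run_px / 2.0) if alive[h]]
        for h in hit:
            alive[h] = False
            out[tuple(coords[h])] = False
        removed += len(hit)
    return out


def _render_boundary(cells: np.ndarray, boundary_width: int) -> np.ndarray:
    bnd = find_boundaries(cells, mode="thick")
    iters = max(0, (boundary_width - 2 + 1) // 2)
    for _ in range(iters):
        bnd = dilation(bnd, footprint=disk(1))
    return bnd


def _place_nuclei(
    labels: np.ndarray, spec: SectionSpec, rng: np.random.Generator
) -> np.ndarray:
    """One nucleus per fiber: peripheral by default, central for a fraction."""
    nucleus_map = np.zeros_like(labels, dtype=np.int32)
    edt = ndimage.distance_transform_edt(labels > 0)
    n_fibers = int(labels.max())
    central = rng.random(n_fibers) < spec.central_nucleation_fraction
    slices = ndimage.find_objects(labels)
    r = spec.nucleus_radius_px
    nucleus_id = 0
    for i in range(1, n_fibers + 1):
        slc = slices[i - 1]
        if slc is None:
            continue
        mask = labels[slc] == i
        dist = np.where(mask, edt[slc], 0.0)
        if central[i - 1]:
            flat = int(np.argmax(dist))
        else:
            # peripheral: just inside the sarcolemma, one radius plus margin in
            ring = mask & (dist >= r + 1) & (dist <= r + 3)
            if not ring.any():
                ring = mask & (dist >= r + 1)
            if not ring.any():
                continue  # fiber too small to host a nucleus
            choices = np.flatnonzero(ring)
            flat = int(choices[rng.integers(choices.size)])
        cy, cx = np.unravel_index(flat, mask.shape)
        cy += slc[0].start
        cx += slc[1].start
        rr, cc = draw_disk((cy, cx), r, shape=labels.shape)
        inside = labels[rr, cc] == i
        if not inside.any():
            continue
        nucleus_id += 1
        nucleus_map[rr[inside], cc[inside]] = nucleus_id
    return nucleus_map


def _prune_to_largest_component(labels: np.ndarray) -> np.ndarray:
    """Keep each fiber's largest 4-connected piece; orphan pixels -> ECM.

    A pixelated convex cell can be connected only diagonally at a thin
    corner; the stray pixels beyond such a pinch are reassigned to
    background so every truth fiber is a single 4-connected object.
    """
    from skimage.measure import label as cc_label

    cc = cc_label(labels, connectivity=1, background=0)
    if cc.max() == labels.max():
        return labels
    sizes = np.bincount(cc.ravel())
    flat_cc, flat_lab = cc.ravel(), labels.ravel()
    first = np.unique(flat_cc, return_index=True)[1]
    owner = np.zeros(cc.max() + 1, dtype=np.int32)
    owner[flat_cc[first]] = flat_lab[first]
    keep = np.zeros(cc.max() + 1, dtype=bool)
    for lab in np.unique(labels):
        if lab == 0:
            continue
        members = np.flatnonzero(owner == lab)
        keep[members[np.argmax(sizes[members])]] = True
    return np.where(keep[cc], labels, 0).astype(np.int32)


def generate_section(spec: SectionSpec) -> tuple[MultiChannelSection, GroundTruth]:
    """Render a synthetic muscle section and its ground truth.

    The returned section holds laminin, four MyHC channels, DAPI, GFP,
    probe and collagen rasters; the ground truth holds the gap-free fiber
    label map, per-fiber noiseless channel means, and the generating
    parameters (types, compositions, GFP flags, nucleus map).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    cells = _tessellate(spec, rng)
    bnd = _render_boundary(cells, spec.boundary_width)
    labels = np.where(bnd, 0, cells).astype(np.int32)
    labels = _prune_to_largest_component(labels)
    bnd_gapped = _delete_gaps(bnd, spec.gap_fraction, spec.gap_run_px, rng)

    n = spec.n_fibers
    types, comp = sample_fiber_compositions(spec.type_profile, n, rng)
    gfp_true = rng.random(n) < spec.gfp_positive_fraction
    nucleus_map = _place_nuclei(labels, spec, rng)

    def per_fiber_raster(values: np.ndarray, background: float) -> np.ndarray:
        lut = np.concatenate([[0.0], values])
        return background + lut[labels]

    clean: dict[str, np.ndarray] = {}
    lam = spec.background(sec.LAMININ) + spec.laminin_amplitude * bnd_gapped.astype(float)
    if spec.laminin_blur_sigma > 0:
        lam = gaussian(lam, sigma=spec.laminin_blur_sigma, preserve_range=True)
    clean[sec.LAMININ] = lam
    for c, channel in enumerate(MYHC_CHANNELS):
        gain = float(spec.channel_gain.get(channel, 1.0))
        clean[channel] = per_fiber_raster(
            spec.myhc_amplitude * gain * comp[:, c], spec.background(channel)
        )
    clean[sec.GFP] = per_fiber_raster(
        spec.gfp_amplitude * gfp_true.astype(float), spec.background(sec.GFP)
    )
    probe_level = spec.probe_base * np.where(gfp_true, spec.probe_effect, 1.0)
    clean[sec.PROBE] = per_fiber_raster(probe_level, spec.background(sec.PROBE))
    clean[sec.DAPI] = spec.background(sec.DAPI) + spec.dapi_amplitude * (
        nucleus_map > 0
    ).astype(float)
    clean[sec.COLLAGEN] = spec.background(sec.COLLAGEN) + (
        spec.collagen_scale * spec.laminin_amplitude * bnd.astype(float)
    )

    index = np.arange(1, n + 1)
    areas = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    truth_rows = {
        "fiber_id": index,
        "area_px": areas,
        "area_um2": areas * spec.pixel_size_um**2,
        "fiber_type": [spec.type_profile.type_names[t] for t in types],
        "gfp_true": gfp_true,
    }
    for c, channel in enumerate(MYHC_CHANNELS):
        truth_rows[f"comp_{channel}"] = comp[:, c]
    truth = pd.DataFrame(truth_rows)
    for channel, raster in clean.items():
        means = ndimage.mean(raster, labels=labels, index=index)
        truth[f"mean_{channel}"] = np.where(areas > 0, means, np.nan)

    noisy = {}
    for channel in sorted(clean):  # fixed order so the noise stream is reproducible
        raster = clean[channel]
        if spec.intensity_noise_sd > 0:
            raster = raster + rng.normal(0.0, spec.intensity_noise_sd, raster.shape)
        noisy[channel] = np.clip(raster, 0.0, None)

    section = MultiChannelSection(
        channels=noisy, pixel_size_um=spec.pixel_size_um, sample=spec.sample
    )
    ground_truth = GroundTruth(
        true_label_map=FiberLabelMap(labels, pixel_size_um=spec.pixel_size_um),
        true_fiber_table=truth,
        true_parameters={
            "seed": spec.seed,
            "n_fibers": spec.n_fibers,
            "gap_fraction": spec.gap_fraction,
            "gfp_positive_fraction": spec.gfp_positive_fraction,
            "probe_effect": spec.probe_effect,
            "intensity_noise_sd": spec.intensity_noise_sd,
            "condition": spec.sample.condition,
        },
        true_nucleus_map=nucleus_map,
    )
    return section, ground_truth


# ---------------------------------------------------------------------------
# qPCR generator
# ---------------------------------------------------------------------------

DEFAULT_TARGET_BASE_CT = 20.0
DEFAULT_HOUSEKEEPING_BASE_CT = 18.0


@dataclass
class GeneSpec:
    """One gene on the synthetic plate.

    ``fold_change`` is the true shPab/Scram expression ratio; housekeeping
    genes are pinned at 1. ``utilization`` maps condition -> distal-PAS
    utilization in (0, 1]; genes without an identified proximal PAS (e.g.
    Murf1) have ``utilization=None`` and only a gene-level primer set.
    """

    name: str
    base_expression: float = 1.0
    fold_change: float = 1.0
    utilization: Mapping[str, float] | None = None
    housekeeping: bool = False
    base_ct: float | None = None
    primer_sets: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.fold_change <= 0 or self.base_expression <= 0:
            raise ValueError(f"{self.name}: expression and fold change must be > 0")
        if self.housekeeping and self.fold_change != 1.0:
            raise ConfigurationError(
                f"housekeeping gene {self.name} must have fold change 1"
            )
        if self.utilization is not None:
            for cond, u in self.utilization.items():
                if not 0.0 < u <= 1.0:
                    raise ValueError(
                        f"{self.name}: utilization for {cond} must lie in (0, 1]"
                    )
        if self.primer_sets is None:
            sets = ["gene_level"]
            if self.utilization is not None:
                sets += ["proximal", "distal"]
            self.primer_sets = tuple(sets)
        if self.utilization is not None and "distal" not in self.primer_sets:
            raise ConfigurationError(
                f"gene {self.name} declares PAS utilization but no distal primer set"
            )

    @property
    def effective_base_ct(self) -> float:
        if self.base_ct is not None:
            return self.base_ct
        return DEFAULT_HOUSEKEEPING_BASE_CT if self.housekeeping else DEFAULT_TARGET_BASE_CT


@dataclass
class QpcrSpec:
    """Design of a synthetic paired qPCR experiment."""

    genes: list[GeneSpec]
    n_mice: int = 5
    replicates: int = 3
    ct_noise_sd: float = 0.2
    mouse_effect_sd: float = 0.5
    effect_condition: str = SHPAB
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mice < 1 or self.replicates < 1:
            raise ValueError("n_mice and replicates must be >= 1")
        if self.ct_noise_sd < 0 or self.mouse_effect_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        names = [g.name for g in self.genes]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate gene names in QpcrSpec")


def default_qpcr_genes() -> list[GeneSpec]:
    """A small plate mirroring the in-vivo design: knocked-down target with
    a distal-PAS shift, an unchanged control gene, and two housekeepers."""
    return [
        GeneSpec(
            "Pabpn1",
            fold_change=0.8,
            utilization={SCRAM: 0.7, SHPAB: 0.7, PBS: 0.7},
        ),
        GeneSpec(
            "Atrogin1",
            fold_change=1.6,
            utilization={SCRAM: 0.7, SHPAB: 0.4, PBS: 0.7},
        ),
        GeneSpec("Murf1", fold_change=1.0),
        GeneSpec("Hprt", housekeeping=True),
        GeneSpec("Gapdh", housekeeping=True),
    ]


def generate_qpcr(spec: QpcrSpec, design: CohortDesign) -> pd.DataFrame:
    """Generate a replicate-level Ct table for a paired cohort.

    Ct model: ``base_ct(gene) - log2(expression) + sample_effect + noise``,
    with the sample effect (cDNA input) shared by every gene of a sample so
    housekeeping normalization cancels it. The proximal primer set reports
    total transcript; the distal set reports total x utilization.
    """
    rng = np.random.default_rng(spec.seed)
    sample_effect = {
        s: rng.normal(0.0, spec.mouse_effect_sd) if spec.mouse_effect_sd > 0 else 0.0
        for s in design.samples["sample"]
    }
    rows = []
    for _, srow in design.samples.iterrows():
        sample, mouse, condition = srow["sample"], srow["mouse"], srow["condition"]
        for gene in spec.genes:
            expr_total = gene.base_expression
            if condition == spec.effect_condition and not gene.housekeeping:
                expr_total *= gene.fold_change
            for primer_set in gene.primer_sets:
                expr = expr_total
                if primer_set == "distal":
                    u = gene.utilization.get(condition) if gene.utilization else None
                    if u is None:
                        raise ConfigurationError(
                            f"gene {gene.name}: no utilization defined for {condition}"
                        )
                    expr = expr_total * u
                base = gene.effective_base_ct - math.log2(expr) + sample_effect[sample]
                for rep in range(1, spec.replicates + 1):
                    noise = rng.normal(0.0, spec.ct_noise_sd) if spec.ct_noise_sd > 0 else 0.0
                    rows.append(
                        {
                            "sample": sample,
                            "mouse": mouse,
                            "condition": condition,
                            "gene": gene.name,
                            "primer_set": primer_set,
                            "replicate": rep,
                            "ct": base + noise,
                            "housekeeping": gene.housekeeping,
                        }
                    )
    return pd.DataFrame(rows)
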