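"""Automated mitotic is-PLA quantification and co-IP interactome post-processing.

The module implements, end to end, the two computational legs of a mitotic
interaction-profiling workflow for importin beta-1 (or any bait):

1. **Imaging leg** — analysis of multi-field, multi-channel z-stack
   fluorescence acquisitions of in-situ proximity ligation assays (is-PLA):
   maximum-intensity projection, background subtraction, threshold
   segmentation of nuclei / mitotic chromosome masses / spindles filtered by
   size and circularity, interphase-vs-mitotic classification by DAPI
   intensity and shape (or phospho-H3 overlap), per-cell PLA sum-intensity
   measurement inside the selected masks, segmentation evaluation against
   ground truth, and a Mann-Whitney comparison of control vs
   importazole-treated conditions.

2. **Interactome leg** — post-processing of MaxQuant-style ``proteinGroups``
   tables from bait vs IgG co-immunoprecipitation: sequential confidence
   filtering (contaminants, decoys, low peptide/MS-MS evidence, ambiguous
   gene association), Welch-test enrichment of bait over IgG with
   down-shifted-normal imputation of missing values, and cross-tabulation of
   hits against a gene→mitotic-phenotype annotation table.

A synthetic-data section generates ground-truthed microscopy scenes and
fixture protein-group tables with the statistical structure both legs
assume, so the whole pipeline can be exercised and benchmarked without any
external data.

The file is organised in the order the pipeline runs:

    section 0  configuration constants, logging, errors
    section 1  synthetic data (scenes, rendering, protein-group fixtures)
    section 2  imaging analysis (projection .. condition comparison)
    section 3  interactome analysis (parsing .. phenotype annotation)
    section 4  pipeline orchestration, manifest, reporting
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy import ndimage, stats
from skimage.filters import threshold_multiotsu, threshold_otsu
from skimage.measure import label as sk_label
from skimage.measure import regionprops
from skimage.restoration import rolling_ball
from statsmodels.stats.multitest import multipletests

# --------------------------------------------------------------------------
# Section 0 — configuration constants, logging, errors
# --------------------------------------------------------------------------

logger = logging.getLogger("mitopla")

#: canonical acquisition channel order: DNA stain, tubulin-or-pH3 IF, PLA.
CHANNELS: tuple[str, str, str] = ("DAPI", "FITC", "TRITC")

#: object classes carried by the ground truth and by detections.
OBJECT_CLASSES: tuple[str, str, str] = (
    "interphase_nucleus",
    "mitotic_chromosomes",
    "spindle",
)

#: phenotype categories of the Mitocheck-style annotation table.
PHENOTYPE_CATEGORIES: tuple[str, ...] = (
    "mitotic_phenotype",
    "nuclear_phenotype",
    "cytokinesis",
    "general_features",
    "annotated_no_phenotype",
)

SCENE_SCHEMA_VERSION = 1

MAX_UINT16 = 65535

_DTYPE = np.float64


class PlacementError(RuntimeError):
    """Raised when the requested cells cannot be placed in the image."""


class SelectionError(ValueError):
    """Raised when a PLA measurement selection is absent for a cell class."""


class PipelineStageError(RuntimeError):
    """Raised when a pipeline stage fails; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage


def configure_logging(level: str = "INFO", logfile: str | Path | None = None) -> None:
    """Attach stderr (and optional file) handlers to the package logger."""
    logger.setLevel(getattr(logging, level.upper()))
    fmt = logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    if not any(isinstance(h, logging.StreamHandler) for h in logger.handlers):
        sh = logging.StreamHandler()
        sh.setFormatter(fmt)
        logger.addHandler(sh)
    if logfile is not None:
        target = str(Path(logfile).resolve())
        for h in list(logger.handlers):
            if isinstance(h, logging.FileHandler) and h.baseFilename == target:
                return
        fh = logging.FileHandler(logfile)
        fh.setFormatter(fmt)
        logger.addHandler(fh)


# --------------------------------------------------------------------------
# Section 1 — synthetic data
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Ellipse:
    """Axis-aligned-then-rotated ellipse in pixel coordinates (y down)."""

    cy: float
    cx: float
    a: float  # semi-axis along the rotated x' direction
    b: float  # semi-axis along the rotated y' direction
    theta: float  # rotation, radians

    def contains(self, y: float, x: float) -> bool:
        ct, st = math.cos(self.theta), math.sin(self.theta)
        dy, dx = y - self.cy, x - self.cx
        u = dx * ct + dy * st
        v = -dx * st + dy * ct
        return (u / self.a) ** 2 + (v / self.b) ** 2 <= 1.0

    def mask(self, yy: np.ndarray, xx: np.ndarray) -> np.ndarray:
        ct, st = math.cos(self.theta), math.sin(self.theta)
        dy, dx = yy - self.cy, xx - self.cx
        u = dx * ct + dy * st
        v = -dx * st + dy * ct
        return (u / self.a) ** 2 + (v / self.b) ** 2 <= 1.0

    @property
    def extent(self) -> float:
        return max(self.a, self.b)


@dataclass
class SceneParams:
    """Acquisition and scene-statistics parameters for the simulator.

    Defaults emulate the acquisition the imaging leg is designed for: a
    pre-defined xy grid of fields, each field a 10-plane z-stack in three
    wavelengths (DAPI / FITC / TRITC), 16-bit camera output.  Structure
    intensities are in arbitrary camera units; the absolute scales are free
    parameters of the simulator (only the contrasts between classes matter
    to the analysis) and were fixed once to plausibly resemble a cooled
    monochrome CCD at moderate exposure.
    """

    field_grid_count: int = 60
    z_planes: int = 10
    channels: tuple[str, str, str] = CHANNELS
    image_size_px: tuple[int, int] = (256, 256)
    pixel_size_um: float = 0.34
    cells_per_field: tuple[int, int] = (5, 9)
    mitotic_fraction: float = 0.06
    condition: str = "CTR"  # or "IPZ"
    ipz_puncta_fold_reduction: float = 5.0
    rng_seed: int = 0

    # intensity scales (arbitrary units, 16-bit range)
    background: tuple[float, float, float] = (200.0, 150.0, 100.0)
    interphase_dapi_peak: tuple[float, float] = (2500.0, 3500.0)
    mitotic_dapi_peak: tuple[float, float] = (6500.0, 9500.0)
    spindle_peak: tuple[float, float] = (5000.0, 7000.0)
    cytoplasm_fitc: float = 400.0
    mitotic_cytoplasm_fitc: float = 300.0

    # PLA puncta statistics
    puncta_per_mitotic: float = 20.0
    puncta_per_interphase: float = 1.5
    punctum_mean_intensity: float = 4000.0
    punctum_log_sigma: float = 0.4
    # spindle / chromosome-periphery / cytoplasm placement of mitotic puncta
    compartment_fractions: tuple[float, float, float] = (0.60, 0.25, 0.15)

    # noise model: Poisson-like photon noise plus Gaussian read noise
    photon_noise_scale: float = 1.0  # 0 disables photon noise
    read_noise_sd: float = 10.0

    # optics: in-focus blur, axial intensity profile, defocus growth
    base_blur_px: float = 0.6
    blur_growth_per_plane: float = 0.45
    axial_sigma_planes: float = 2.2
    spot_sigma_px: float = 1.2
    spot_blur_growth: float = 0.8
    spot_axial_decay: float = 0.15  # puncta fade fast away from focus

    def validate(self) -> None:
        if self.z_planes < 1:
            raise ValueError("z_planes must be >= 1")
        if len(self.channels) != 3:
            raise ValueError("exactly 3 channels are required")
        if not 0.0 <= self.mitotic_fraction <= 1.0:
            raise ValueError("mitotic_fraction must be in [0, 1]")
        if self.ipz_puncta_fold_reduction < 1.0:
            raise ValueError("ipz_puncta_fold_reduction must be >= 1")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        lo, hi = self.cells_per_field
        if lo < 0 or hi < lo:
            raise ValueError("cells_per_field must be a non-negative (lo, hi) range")
        if self.condition not in ("CTR", "IPZ"):
            raise ValueError("condition must be 'CTR' or 'IPZ'")
        if self.field_grid_count < 1:
            raise ValueError("field_grid_count must be >= 1")


@dataclass
class SceneObject:
    """A ground-truth structure: nucleus, chromosome mass or spindle."""

    object_id: int
    cell_id: int
    field: int
    klass: str  # one of OBJECT_CLASSES
    channel: str
    ellipses: tuple[Ellipse, ...]
    peak_intensity: float

    @property
    def centroid(self) -> tuple[float, float]:
        cy = float(np.mean([e.cy for e in self.ellipses]))
        cx = float(np.mean([e.cx for e in self.ellipses]))
        return cy, cx

    def contains(self, y: float, x: float) -> bool:
        return any(e.contains(y, x) for e in self.ellipses)

    @property
    def extent(self) -> float:
        cy, cx = self.centroid
        return max(
            math.hypot(e.cy - cy, e.cx - cx) + e.extent for e in self.ellipses
        )

    def rasterize(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean mask of the analytic shape on the full image grid."""
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        out = np.zeros(shape, bool)
        for e in self.ellipses:
            out |= e.mask(yy, xx)
        return out


@dataclass
class Punctum:
    """A PLA amplification product (diffraction-limited spot)."""

    cell_id: int
    field: int
    y: float
    x: float
    z: int  # in-focus plane index
    integrated_intensity: float
    compartment: str  # spindle | chromosome_periphery | cytoplasm | nucleus


@dataclass
class GroundTruthScene:
    """Simulator output: the object list that evaluation treats as truth."""

    params: SceneParams
    condition: str
    seed: int
    field_focus: list[float]
    objects: list[SceneObject]
    puncta: list[Punctum]

    def objects_in_field(self, f: int) -> list[SceneObject]:
        return [o for o in self.objects if o.field == f]

    def puncta_in_field(self, f: int) -> list[Punctum]:
        return [p for p in self.puncta if p.field == f]

    # ---- JSON round trip (schema versioned) ----
    def to_dict(self) -> dict:
        return {
            "schema_version": SCENE_SCHEMA_VERSION,
            "condition": self.condition,
            "seed": self.seed,
            "field_focus": list(self.field_focus),
            "params": dataclasses.asdict(self.params),
            "objects": [
                {
                    "object_id": o.object_id,
                    "cell_id": o.cell_id,
                    "field": o.field,
                    "class": o.klass,
                    "channel": o.channel,
                    "ellipses": [dataclasses.asdict(e) for e in o.ellipses],
                    "peak_intensity": o.peak_intensity,
                }
                for o in self.objects
            ],
            "puncta": [dataclasses.asdict(p) for p in self.puncta],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruthScene":
        if d.get("schema_version") != SCENE_SCHEMA_VERSION:
            raise ValueError(f"unsupported scene schema: {d.get('schema_version')}")
        params = _dataclass_from_dict(SceneParams, d["params"])
        objects = [
            SceneObject(
                object_id=o["object_id"],
                cell_id=o["cell_id"],
                field=o["field"],
                klass=o["class"],
                channel=o["channel"],
                ellipses=tuple(Ellipse(**e) for e in o["ellipses"]),
                peak_intensity=o["peak_intensity"],
            )
            for o in d["objects"]
        ]
        puncta = [Punctum(**p) for p in d["puncta"]]
        return cls(
            params=params,
            condition=d["condition"],
            seed=d["seed"],
            field_focus=list(d["field_focus"]),
            objects=objects,
            puncta=puncta,
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "GroundTruthScene":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _place_cells(
    rng: np.random.Generator,
    n: int,
    shape: tuple[int, int],
    margin: float = 30.0,
    min_dist: float = 50.0,
    max_tries: int = 2000,
) -> list[tuple[float, float]]:
    """Rejection-sample non-overlapping cell centres within the field."""
    h, w = shape
    if n == 0:
        return []
    if h - 2 * margin <= 0 or w - 2 * margin <= 0:
        raise PlacementError(
            f"image {shape} too small to place cells with margin {margin}"
        )
    centres: list[tuple[float, float]] = []
    for _ in range(n):
        for _try in range(max_tries):
            y = rng.uniform(margin, h - margin)
            x = rng.uniform(margin, w - margin)
            if all(math.hypot(y - cy, x - cx) >= min_dist for cy, cx in centres):
                centres.append((y, x))
                break
        else:
            raise PlacementError(
                f"could not place {n} cells in a {shape} field "
                f"(min distance {min_dist}px); reduce cells_per_field"
            )
    return centres


def _sample_in_ellipse(rng: np.random.Generator, e: Ellipse) -> tuple[float, float]:
    r = math.sqrt(rng.random())
    phi = rng.uniform(0.0, 2.0 * math.pi)
    u = r * e.a * math.cos(phi)
    v = r * e.b * math.sin(phi)
    ct, st = math.cos(e.theta), math.sin(e.theta)
    return e.cy + u * st + v * ct, e.cx + u * ct - v * st


def generate_ground_truth(params: SceneParams) -> GroundTruthScene:
    """Sample the object/puncta lists of a scene (no rendering).

    Interphase nuclei are near-round ellipses of moderate DAPI intensity;
    mitotic chromosome masses are irregular unions of 2–4 elongated ellipses
    with distinctly higher DAPI peak intensity; every mitotic cell carries a
    bright compact spindle in the tubulin channel. PLA puncta are placed on
    the spindle, the chromosome periphery or the cytoplasm of mitotic cells
    (and sparsely on interphase cells); the importazole (IPZ) condition
    divides the expected per-cell puncta count by the configured fold.
    """
    params.validate()
    rng = np.random.default_rng([params.rng_seed, 1])
    h, w = params.image_size_px
    fold = params.ipz_puncta_fold_reduction if params.condition == "IPZ" else 1.0
    lam_mitotic = params.puncta_per_mitotic / fold

    objects: list[SceneObject] = []
    puncta: list[Punctum] = []
    field_focus: list[float] = []
    oid = 0
    cid = 0
    zmid = (params.z_planes - 1) / 2.0

    for f in range(params.field_grid_count):
        focus = zmid + rng.uniform(-0.5, 0.5)
        field_focus.append(float(focus))
        lo, hi = params.cells_per_field
        n_cells = int(rng.integers(lo, hi + 1))
        centres = _place_cells(rng, n_cells, (h, w))
        for cy, cx in centres:
            mitotic = rng.random() < params.mitotic_fraction
            if not mitotic:
                r = rng.uniform(14.0, 20.0)
                ratio = rng.uniform(0.85, 1.0)
                theta = rng.uniform(0.0, math.pi)
                nucleus = SceneObject(
                    object_id=oid,
                    cell_id=cid,
                    field=f,
                    klass="interphase_nucleus",
                    channel="DAPI",
                    ellipses=(Ellipse(cy, cx, r, r * ratio, theta),),
                    peak_intensity=float(rng.uniform(*params.interphase_dapi_peak)),
                )
                objects.append(nucleus)
                oid += 1
                n_p = int(rng.poisson(params.puncta_per_interphase))
                for _ in range(n_p):
                    if rng.random() < 0.5:
                        py, px = _sample_in_ellipse(rng, nucleus.ellipses[0])
                        comp = "nucleus"
                    else:
                        ang = rng.uniform(0, 2 * math.pi)
                        rad = r * rng.uniform(1.2, 1.8)
                        py, px = cy + rad * math.sin(ang), cx + rad * math.cos(ang)
                        comp = "cytoplasm"
                    puncta.append(
                        _make_punctum(rng, params, cid, f, py, px, focus, comp, (h, w))
                    )
            else:
                # chromosome mass: irregular union of elongated ellipses
                k = int(rng.integers(3, 6))
                base_r = rng.uniform(10.0, 14.0)
                angles = rng.uniform(0, math.pi, size=k) + np.arange(k) * math.pi / k
                parts = []
                for j in range(k):
                    off = rng.uniform(0.5, 0.9) * base_r
                    ang = rng.uniform(0, 2 * math.pi)
                    ecy = cy + off * math.sin(ang)
                    ecx = cx + off * math.cos(ang)
                    a = base_r * rng.uniform(0.8, 1.1)
                    b = a * rng.uniform(0.35, 0.55)
                    parts.append(Ellipse(ecy, ecx, a, b, float(angles[j])))
                chrom = SceneObject(
                    object_id=oid,
                    cell_id=cid,
                    field=f,
                    klass="mitotic_chromosomes",
                    channel="DAPI",
                    ellipses=tuple(parts),
                    peak_intensity=float(rng.uniform(*params.mitotic_dapi_peak)),
                )
                objects.append(chrom)
                oid += 1
                sa = rng.uniform(16.0, 22.0)
                sb = sa * rng.uniform(0.45, 0.65)
                stheta = rng.uniform(0.0, math.pi)
                jy, jx = rng.uniform(-3, 3), rng.uniform(-3, 3)
                spindle = SceneObject(
                    object_id=oid,
                    cell_id=cid,
                    field=f,
                    klass="spindle",
                    channel="FITC",
                    ellipses=(Ellipse(cy + jy, cx + jx, sa, sb, stheta),),
                    peak_intensity=float(rng.uniform(*params.spindle_peak)),
                )
                objects.append(spindle)
                oid += 1
                n_p = int(rng.poisson(lam_mitotic))
                fr = params.compartment_fractions
                chrom_extent = chrom.extent
                for _ in range(n_p):
                    u = rng.random()
                    if u < fr[0]:
                        py, px = _sample_in_ellipse(rng, spindle.ellipses[0])
                        comp = "spindle"
                    elif u < fr[0] + fr[1]:
                        ang = rng.uniform(0, 2 * math.pi)
                        rad = chrom_extent * rng.uniform(1.05, 1.4)
                        py, px = cy + rad * math.sin(ang), cx + rad * math.cos(ang)
                        comp = "chromosome_periphery"
                    else:
                        ang = rng.uniform(0, 2 * math.pi)
                        rad = chrom_extent * rng.uniform(1.6, 2.4)
                        py, px = cy + rad * math.sin(ang), cx + rad * math.cos(ang)
                        comp = "cytoplasm"
                    puncta.append(
                        _make_punctum(rng, params, cid, f, py, px, focus, comp, (h, w))
                    )
            cid += 1

    return GroundTruthScene(
        params=params,
        condition=params.condition,
        seed=params.rng_seed,
        field_focus=field_focus,
        objects=objects,
        puncta=puncta,
    )


def _make_punctum(rng, params, cid, f, py, px, focus, comp, shape) -> Punctum:
    h, w = shape
    py = float(np.clip(py, 6.0, h - 7.0))
    px = float(np.clip(px, 6.0, w - 7.0))
    z = int(np.clip(round(focus + rng.normal(0.0, 1.2)), 0, params.z_planes - 1))
    mu = math.log(params.punctum_mean_intensity) - 0.5 * params.punctum_log_sigma**2
    inten = float(rng.lognormal(mu, params.punctum_log_sigma))
    return Punctum(cid, f, py, px, z, inten, comp)


def _add_spot(plane: np.ndarray, y: float, x: float, sigma: float, flux: float) -> None:
    """Add a discretely normalised Gaussian spot (window-renormalised)."""
    h, w = plane.shape
    r = max(3, int(math.ceil(4.0 * sigma)))
    y0, y1 = max(0, int(y) - r), min(h, int(y) + r + 1)
    x0, x1 = max(0, int(x) - r), min(w, int(x) + r + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    k = np.exp(-((yy - y) ** 2 + (xx - x) ** 2) / (2.0 * sigma**2))
    s = k.sum()
    if s > 0:
        plane[y0:y1, x0:x1] += flux * k / s


def render_acquisition(scene: GroundTruthScene, params: SceneParams) -> np.ndarray:
    """Render a scene into a (fields, z, channels, y, x) uint16 stack.

    Extended structures are drawn at their peak intensity with a soft edge,
    then propagated along z with a Gaussian axial intensity profile and a
    defocus blur growing linearly with the distance from the field's focal
    plane.  Each punctum is a diffraction-limited Gaussian spot carrying its
    full integrated intensity at its in-focus plane, plus faint blurred
    ghosts on the adjacent planes; the per-punctum plane weights are
    normalised so the total rendered flux equals the punctum's integrated
    intensity (photon-flux conservation).  Poisson-like photon noise and
    Gaussian read noise are added per plane, and the result is clipped into
    the 16-bit range.
    """
    params.validate()
    h, w = params.image_size_px
    nf, nz = params.field_grid_count, params.z_planes
    rng = np.random.default_rng([params.rng_seed, 2])
    stack = np.empty((nf, nz, 3, h, w), dtype=np.uint16)

    for f in range(nf):
        focus = scene.field_focus[f] if f < len(scene.field_focus) else (nz - 1) / 2.0
        base = {c: np.zeros((h, w), dtype=_DTYPE) for c in params.channels}

        # faint cytoplasm in the tubulin channel so interphase cells are
        # visible there without standing out like spindles
        for o in scene.objects_in_field(f):
            if o.klass == "interphase_nucleus":
                e = o.ellipses[0]
                halo = Ellipse(e.cy, e.cx, e.a * 1.9, e.b * 1.9, e.theta)
                yy, xx = np.mgrid[0:h, 0:w]
                np.maximum(
                    base["FITC"],
                    halo.mask(yy, xx) * params.cytoplasm_fitc,
                    out=base["FITC"],
                )
            elif o.klass == "spindle":
                e = o.ellipses[0]
                halo = Ellipse(e.cy, e.cx, e.a * 1.4, e.a * 1.3, e.theta)
                yy, xx = np.mgrid[0:h, 0:w]
                np.maximum(
                    base["FITC"],
                    halo.mask(yy, xx) * params.mitotic_cytoplasm_fitc,
                    out=base["FITC"],
                )

        for o in scene.objects_in_field(f):
            img = base[o.channel]
            yy, xx = np.mgrid[0:h, 0:w]
            m = np.zeros((h, w), bool)
            for e in o.ellipses:
                m |= e.mask(yy, xx)
            np.maximum(img, m * o.peak_intensity, out=img)

        # soft edges of the in-focus structures
        for c in ("DAPI", "FITC"):
            base[c] = ndimage.gaussian_filter(base[c], 1.5)

        field_puncta = scene.puncta_in_field(f)

        for z in range(nz):
            dz = abs(z - focus)
            axial = math.exp(-0.5 * (dz / params.axial_sigma_planes) ** 2)
            blur = params.base_blur_px + params.blur_growth_per_plane * dz
            for ci, c in enumerate(params.channels):
                if c == "TRITC":
                    plane = np.zeros((h, w), dtype=_DTYPE)
                else:
                    plane = ndimage.gaussian_filter(base[c], blur) * axial
                plane += params.background[ci]
                stack_plane = plane
                if c == "TRITC" and field_puncta:
                    _render_puncta_plane(stack_plane, field_puncta, z, params)
                # noise model: Poisson photon noise + Gaussian read noise
                g = params.photon_noise_scale
                if g > 0:
                    noisy = rng.poisson(np.clip(stack_plane, 0, None) * g) / g
                else:
                    noisy = stack_plane
                if params.read_noise_sd > 0:
                    noisy = noisy + rng.normal(0.0, params.read_noise_sd, (h, w))
                stack[f, z, ci] = np.clip(np.rint(noisy), 0, MAX_UINT16).astype(
                    np.uint16
                )
    return stack


def _render_puncta_plane(
    plane: np.ndarray, puncta: Sequence[Punctum], z: int, params: SceneParams
) -> None:
    for p in puncta:
        dz = abs(z - p.z)
        if dz > 1:
            continue
        # plane weights over {z-1, z, z+1}, normalised within the stack
        zs = [p.z + d for d in (-1, 0, 1) if 0 <= p.z + d < params.z_planes]
        ws = np.array([math.exp(-abs(zz - p.z) / params.spot_axial_decay) for zz in zs])
        ws = ws / ws.sum()
        wz = float(ws[zs.index(z)]) if z in zs else 0.0
        if wz <= 0:
            continue
        sigma = params.spot_sigma_px + params.spot_blur_growth * dz
        _add_spot(plane, p.y, p.x, sigma, p.integrated_intensity * wz)


def generate_scene(params: SceneParams) -> tuple[GroundTruthScene, np.ndarray]:
    """Generate a ground-truthed scene and its rendered acquisition stack."""
    scene = generate_ground_truth(params)
    stack = render_acquisition(scene, params)
    return scene, stack


def ground_truth_stats(scene: GroundTruthScene) -> pd.DataFrame:
    """Per-object class, peak intensity and rasterized-shape circularity.

    Circularity is measured on the analytic mask with the same estimator
    the segmentation uses, so the generator's class contrast can be checked
    directly against the premise the classifier relies on.
    """
    rows = []
    for o in scene.objects:
        cy, cx = o.centroid
        ext = int(math.ceil(o.extent)) + 3
        yy, xx = np.mgrid[-ext:ext, -ext:ext]
        m = np.zeros(yy.shape, bool)
        for e in o.ellipses:
            m |= e.mask(yy + cy, xx + cx)
        props = regionprops(m.astype(np.uint8))
        circ = _circularity(props[0].area, props[0].perimeter) if props else 1.0
        rows.append(
            {
                "object_id": o.object_id,
                "class": o.klass,
                "channel": o.channel,
                "peak_intensity": o.peak_intensity,
                "circularity": circ,
            }
        )
    return pd.DataFrame(rows)


# ---- stack I/O -----------------------------------------------------------


def write_stack(path: str | Path, stack: np.ndarray, pixel_size_um: float = 0.34) -> None:
    """Write a (fields, z, channels, y, x) stack as a multi-page TIFF."""
    res = 1.0 / pixel_size_um
    tifffile.imwrite(
        str(path),
        stack,
        resolution=(res, res),
        metadata={"axes": "SZCYX", "pixel_size_um": pixel_size_um},
    )


def read_stack(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(str(path))
    if arr.ndim != 5:
        raise ValueError(f"expected a 5D field/z/channel stack, got shape {arr.shape}")
    return arr


# ---- protein-group fixtures ---------------------------------------------

#: MaxQuant-dialect columns the interactome leg requires.
REQUIRED_PG_COLUMNS = (
    "Protein IDs",
    "Gene names",
    "Unique peptides",
    "Peptides",
    "MS/MS count",
    "Only identified by site",
    "Reverse",
    "Potential contaminant",
)


@dataclass
class ProteinGroupFixtureParams:
    """Composition of a synthetic proteinGroups table with planted truth."""

    n_background: int = 300
    n_true_interactors: int = 40
    n_contaminants: int = 8
    n_reverse: int = 6
    n_only_by_site: int = 5
    n_low_peptide: int = 12
    n_low_msms: int = 10
    n_multigene: int = 6
    bait_log2_enrichment_mean: float = 4.0
    bait_log2_enrichment_sd: float = 0.5
    replicates: int = 3
    missing_rate_igg: float = 0.3
    # true interactors are depleted in the IgG pull-down: their observed IgG
    # log2 intensities sit near the detection limit, which is also why they
    # go missing (missing-not-at-random, as in real label-free co-IP data)
    igg_log2_depletion: float = 3.0
    base_log2_mean: float = 25.0
    base_log2_sd: float = 1.5
    replicate_log2_sd: float = 0.4
    rng_seed: int = 0

    def validate(self) -> None:
        for name in (
            "n_background",
            "n_true_interactors",
            "n_contaminants",
            "n_reverse",
            "n_only_by_site",
            "n_low_peptide",
            "n_low_msms",
            "n_multigene",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.replicates < 2:
            raise ValueError("replicates must be >= 2")
        if not 0.0 <= self.missing_rate_igg <= 1.0:
            raise ValueError("missing_rate_igg must be in [0, 1]")


def bait_sample_names(replicates: int = 3) -> list[str]:
    return [f"IP_{i + 1}" for i in range(replicates)]


def control_sample_names(replicates: int = 3) -> list[str]:
    return [f"IgG_{i + 1}" for i in range(replicates)]


def generate_protein_groups(
    params: ProteinGroupFixtureParams,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit a MaxQuant-dialect proteinGroups table plus truth labels.

    Background proteins bind bait and IgG pull-downs equally; planted true
    interactors are log2-enriched in the bait samples and partially missing
    (zero intensity) in the IgG samples.  Each violator class breaks exactly
    one confidence-filter rule so planted counts reconcile with the
    sequential filter report.  Returns ``(table, truth)`` where truth maps
    each group id to its planted role.
    """
    params.validate()
    rng = np.random.default_rng([params.rng_seed, 3])
    bait = bait_sample_names(params.replicates)
    ctrl = control_sample_names(params.replicates)
    rows: list[dict] = []
    truth: list[dict] = []
    counter = [0]

    def base_counts(r):
        peptides = int(r.integers(3, 16))
        unique = int(r.integers(2, peptides + 1))
        msms = int(r.integers(max(3, peptides), 6 * peptides))
        return unique, peptides, msms

    def intensities(r, enriched: bool, missing_igg: bool):
        base = r.normal(params.base_log2_mean, params.base_log2_sd)
        out = {}
        shift = (
            r.normal(params.bait_log2_enrichment_mean, params.bait_log2_enrichment_sd)
            if enriched
            else 0.0
        )
        for s in bait:
            out[f"Intensity {s}"] = 2.0 ** (
                base + shift + r.normal(0.0, params.replicate_log2_sd)
            )
        depletion = params.igg_log2_depletion if enriched else 0.0
        for s in ctrl:
            if missing_igg and r.random() < params.missing_rate_igg:
                out[f"Intensity {s}"] = 0.0
            else:
                out[f"Intensity {s}"] = 2.0 ** (
                    base - depletion + r.normal(0.0, params.replicate_log2_sd)
                )
        return out

    def add_row(role: str, **overrides):
        i = counter[0]
        counter[0] += 1
        unique, peptides, msms = base_counts(rng)
        row = {
            "Protein IDs": f"P{i:05d}",
            "Gene names": f"GENE{i:04d}",
            "Unique peptides": unique,
            "Peptides": peptides,
            "MS/MS count": msms,
            "Only identified by site": "",
            "Reverse": "",
            "Potential contaminant": "",
        }
        row.update(
            intensities(
                rng,
                enriched=(role == "true_interactor"),
                missing_igg=(role == "true_interactor"),
            )
        )
        row.update(overrides)
        rows.append(row)
        truth.append({"group_id": row["Protein IDs"], "role": role})

    for _ in range(params.n_background):
        add_row("background")
    for _ in range(params.n_true_interactors):
        add_row("true_interactor")
    for _ in range(params.n_contaminants):
        add_row("contaminant", **{"Potential contaminant": "+"})
    for _ in range(params.n_reverse):
        add_row("reverse", **{"Reverse": "+"})
    for _ in range(params.n_only_by_site):
        add_row("only_by_site", **{"Only identified by site": "+"})
    for _ in range(params.n_low_peptide):
        add_row("low_peptide", **{"Unique peptides": 1, "Peptides": 1})
    for _ in range(params.n_low_msms):
        # enough peptides, too few spectra
        add_row("low_msms", **{"Unique peptides": 2, "Peptides": 2, "MS/MS count": 2})
    for i in range(params.n_multigene):
        gid = counter[0]
        add_row("multi_gene", **{"Gene names": f"GENE{gid:04d};ALT{gid:04d}"})

    table = pd.DataFrame(rows)
    return table, pd.DataFrame(truth)


def write_protein_groups(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def generate_annotation_table(
    genes: Iterable[str],
    rng_seed: int = 0,
    annotated_fraction: float = 195 / 272,
    category_weights: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Mitocheck-like gene→phenotype table over the given genes.

    Default category weights follow the proportions observed when a mitotic
    bait interactome was cross-referenced against the Mitocheck screen
    (mitotic 86 : nuclear 7 : cytokinesis 10 : general 51 : no-phenotype 41
    out of 195 annotated genes).
    """
    if category_weights is None:
        category_weights = {
            "mitotic_phenotype": 86,
            "nuclear_phenotype": 7,
            "cytokinesis": 10,
            "general_features": 51,
            "annotated_no_phenotype": 41,
        }
    cats = list(category_weights)
    w = np.array([category_weights[c] for c in cats], dtype=float)
    w = w / w.sum()
    rng = np.random.default_rng([rng_seed, 4])
    rows = []
    for g in genes:
        if rng.random() < annotated_fraction:
            rows.append({"gene": g, "category": cats[int(rng.choice(len(cats), p=w))]})
    return pd.DataFrame(rows, columns=["gene", "category"])


# --------------------------------------------------------------------------
# Section 2 — imaging analysis
# --------------------------------------------------------------------------


@dataclass
class ProjectedImage:
    """Per-channel 2D rasters plus provenance of the projection."""

    channels: dict[str, np.ndarray]
    provenance: dict = field(default_factory=dict)

    def channel(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise KeyError(f"channel '{name}' not present (have {list(self.channels)})")
        return self.channels[name]


def max_intensity_projection(
    stack: np.ndarray, field_index: int, channel_names: Sequence[str] = CHANNELS
) -> ProjectedImage:
    """Maximum-intensity projection over z for one field of a 5D stack."""
    if not 0 <= field_index < stack.shape[0]:
        raise IndexError(f"field {field_index} out of range [0, {stack.shape[0]})")
    if stack.shape[1] == 0:
        raise ValueError("stack has an empty z axis")
    proj = stack[field_index].max(axis=0).astype(_DTYPE)
    chans = {name: proj[i] for i, name in enumerate(channel_names)}
    return ProjectedImage(channels=chans, provenance={"field": field_index})


def subtract_background(
    img: ProjectedImage,
    method: str = "percentile",
    value: float = 0.0,
    q: float = 50.0,
    radius: float = 25.0,
) -> ProjectedImage:
    """Per-channel background subtraction; output clipped at zero.

    methods: ``constant`` (subtract ``value``), ``percentile`` (subtract the
    ``q``-th percentile of the channel, the default — robust as long as the
    background dominates the pixel population), ``rolling_ball`` (spatially
    varying background with ball ``radius``).
    """
    out = {}
    for name, arr in img.channels.items():
        a = arr.astype(_DTYPE)
        if method == "constant":
            bg = value
        elif method == "percentile":
            bg = np.percentile(a, q)
        elif method == "rolling_ball":
            bg = rolling_ball(a, radius=radius)
        else:
            raise ValueError(f"unknown background method '{method}'")
        out[name] = np.clip(a - bg, 0.0, None)
    prov = dict(img.provenance)
    prov["background"] = method
    return ProjectedImage(channels=out, provenance=prov)


def _circularity(area: float, perimeter: float) -> float:
    """4πA/P² with the contour-length perimeter estimator, clamped to 1."""
    if perimeter <= 0:
        return 1.0
    return min(1.0, 4.0 * math.pi * area / perimeter**2)


@dataclass
class CategoryParams:
    """Segmentation rules for one object category."""

    channel: str
    intensity_threshold: float | str = "otsu"  # value | otsu | multiotsu_high
    min_area_px: int = 1
    max_area_px: int = 10**9
    min_circularity: float = 0.0
    max_circularity: float = 1.0

    def validate(self) -> None:
        if not 0.0 <= self.min_circularity <= self.max_circularity:
            raise ValueError("require 0 <= min_circularity <= max_circularity")
        if self.min_area_px < 1:
            raise ValueError("min_area_px must be >= 1")


@dataclass
class SegmentationParams:
    """Per-category segmentation rules (intensity, size, circularity)."""

    categories: dict[str, CategoryParams] = field(default_factory=dict)

    def validate(self) -> None:
        for cp in self.categories.values():
            cp.validate()


def default_segmentation_params() -> SegmentationParams:
    """Default thresholds, calibrated once on the synthetic generator.

    Fixed intensity thresholds (in background-subtracted a.u.) mirror the
    save-and-reload threshold workflow of interactive acquisition software;
    per-image auto-thresholds ("otsu", "multiotsu_high") remain available
    as overrides.
    """
    return SegmentationParams(
        categories={
            "interphase_nucleus": CategoryParams(
                channel="DAPI",
                intensity_threshold=1200.0,
                min_area_px=250,
                max_area_px=2600,
                min_circularity=0.80,
                max_circularity=1.0,
            ),
            "mitotic_chromosomes": CategoryParams(
                channel="DAPI",
                intensity_threshold=1200.0,
                min_area_px=120,
                max_area_px=3000,
                min_circularity=0.0,
                max_circularity=0.95,
            ),
            "spindle": CategoryParams(
                channel="FITC",
                intensity_threshold=2200.0,
                min_area_px=180,
                max_area_px=3200,
                min_circularity=0.20,
                max_circularity=1.0,
            ),
        }
    )


@dataclass
class LabeledMask:
    """Labelled connected components for one category, with measurements.

    ``props`` is indexed by label and carries area, perimeter, circularity,
    centroid, intensity statistics and major axis length measured on the
    channel the category was segmented from, so downstream classification
    needs no further image access.
    """

    category: str
    labels: np.ndarray
    props: pd.DataFrame

    @property
    def n_objects(self) -> int:
        return len(self.props)

    def region(self, lab: int) -> np.ndarray:
        return self.labels == lab


def _measure_labels(labels: np.ndarray, intensity: np.ndarray) -> pd.DataFrame:
    rows = []
    for rp in regionprops(labels, intensity_image=intensity):
        rows.append(
            {
                "label": rp.label,
                "area": float(rp.area),
                "perimeter": float(rp.perimeter),
                "circularity": _circularity(rp.area, rp.perimeter),
                "y": float(rp.centroid[0]),
                "x": float(rp.centroid[1]),
                "mean_intensity": float(rp.intensity_mean),
                "max_intensity": float(rp.intensity_max),
                "major_axis_length": float(rp.axis_major_length),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "label",
            "area",
            "perimeter",
            "circularity",
            "y",
            "x",
            "mean_intensity",
            "max_intensity",
            "major_axis_length",
        ],
    )
    return df.set_index("label")


def _resolve_threshold(arr: np.ndarray, spec: float | str) -> float:
    if isinstance(spec, (int, float)):
        return float(spec)
    if spec == "otsu":
        return float(threshold_otsu(arr))
    if spec == "multiotsu_high":
        return float(threshold_multiotsu(arr, classes=3)[-1])
    raise ValueError(f"unknown intensity threshold '{spec}'")


def segment_category(
    img: ProjectedImage, params: SegmentationParams, category: str
) -> LabeledMask:
    """Threshold + 8-connected labelling + size/circularity filtering."""
    if category not in params.categories:
        raise KeyError(f"no segmentation rules for category '{category}'")
    cp = params.categories[category]
    cp.validate()
    arr = img.channel(cp.channel)
    thr = _resolve_threshold(arr, cp.intensity_threshold)
    labels = sk_label(arr > thr, connectivity=2)
    props = _measure_labels(labels, arr)
    keep = props[
        (props["area"] >= cp.min_area_px)
        & (props["area"] <= cp.max_area_px)
        & (props["circularity"] >= cp.min_circularity)
        & (props["circularity"] <= cp.max_circularity)
    ]
    out = np.zeros_like(labels)
    for new, lab in enumerate(keep.index, start=1):
        out[labels == lab] = new
    props_out = keep.reset_index(drop=True)
    props_out.index = pd.RangeIndex(1, len(props_out) + 1, name="label")
    return LabeledMask(category=category, labels=out, props=props_out)


def segment_dapi(img: ProjectedImage, params: SegmentationParams) -> LabeledMask:
    """All DAPI objects passing either the interphase or the mitotic filter.

    The two DAPI categories share one thresholding/labelling pass; a
    component is retained if it satisfies at least one category's size and
    circularity window, and the interphase/mitotic call is deferred to
    :func:`classify_cells`.
    """
    cats = [
        params.categories[c]
        for c in ("interphase_nucleus", "mitotic_chromosomes")
        if c in params.categories
    ]
    if not cats:
        raise KeyError("need interphase_nucleus / mitotic_chromosomes rules")
    arr = img.channel(cats[0].channel)
    thr = _resolve_threshold(arr, cats[0].intensity_threshold)
    labels = sk_label(arr > thr, connectivity=2)
    props = _measure_labels(labels, arr)
    keep_mask = np.zeros(len(props), bool)
    for cp in cats:
        keep_mask |= (
            (props["area"] >= cp.min_area_px)
            & (props["area"] <= cp.max_area_px)
            & (props["circularity"] >= cp.min_circularity)
            & (props["circularity"] <= cp.max_circularity)
        ).to_numpy()
    keep = props[keep_mask]
    out = np.zeros_like(labels)
    for new, lab in enumerate(keep.index, start=1):
        out[labels == lab] = new
    props_out = keep.reset_index(drop=True)
    props_out.index = pd.RangeIndex(1, len(props_out) + 1, name="label")
    return LabeledMask(category="dapi", labels=out, props=props_out)


def write_mask(path: str | Path, mask: LabeledMask) -> None:
    """Persist a label raster as 16-bit TIFF (measurements are re-derived)."""
    tifffile.imwrite(str(path), mask.labels.astype(np.uint16))


def read_mask(
    path: str | Path, category: str, intensity: np.ndarray
) -> LabeledMask:
    labels = tifffile.imread(str(path)).astype(np.int32)
    return LabeledMask(category=category, labels=labels, props=_measure_labels(labels, intensity))


@dataclass
class ClassifyParams:
    """Interphase/mitotic decision rules (calibrated on the generator)."""

    mitotic_intensity_min: float = 4000.0  # mean DAPI a.u. within the mask
    mitotic_circularity_max: float = 0.95
    intensity_stat: str = "mean"  # or "max"
    spindle_link_factor: float = 1.5  # × mean spindle major axis
    ph3_overlap_min_fraction: float = 0.25


@dataclass
class CellRecord:
    """One classified cell with its masks and PLA readout."""

    cell_id: int
    field: int
    klass: str  # "interphase" | "mitotic"
    dapi_label: int
    spindle_label: int | None
    centroid: tuple[float, float]
    pla_sum_intensity: float | None = None


def classify_cells(
    dapi_masks: LabeledMask,
    spindle_masks: LabeledMask,
    params: ClassifyParams | None = None,
    ph3_masks: LabeledMask | None = None,
    field_index: int = 0,
) -> tuple[list[CellRecord], list[int]]:
    """Classify DAPI objects as interphase or mitotic and link spindles.

    A DAPI object is mitotic iff its intensity statistic exceeds the mitotic
    intensity floor AND its circularity is below the mitotic ceiling, OR it
    overlaps a pH3-positive mask.  Each mitotic object links the nearest
    unassigned spindle whose centroid lies within ``spindle_link_factor``
    times the mean spindle major axis; equidistant candidates are broken
    deterministically toward the lowest spindle label (logged).  Returns the
    records and the labels of spindles left unlinked.
    """
    if params is None:
        params = ClassifyParams()
    stat_col = "mean_intensity" if params.intensity_stat == "mean" else "max_intensity"

    spin_props = spindle_masks.props
    if len(spin_props):
        link_dist = params.spindle_link_factor * float(
            spin_props["major_axis_length"].mean()
        )
    else:
        link_dist = 0.0

    records: list[CellRecord] = []
    assigned: set[int] = set()
    cid = 0
    for lab, row in dapi_masks.props.iterrows():
        mitotic = (
            row[stat_col] >= params.mitotic_intensity_min
            and row["circularity"] <= params.mitotic_circularity_max
        )
        if not mitotic and ph3_masks is not None and ph3_masks.n_objects:
            region = dapi_masks.region(int(lab))
            overlap = np.count_nonzero(region & (ph3_masks.labels > 0))
            if overlap >= params.ph3_overlap_min_fraction * region.sum():
                mitotic = True
        spindle_label: int | None = None
        if mitotic and len(spin_props):
            cands = []
            for slab, srow in spin_props.iterrows():
                if slab in assigned:
                    continue
                d = math.hypot(srow["y"] - row["y"], srow["x"] - row["x"])
                if d <= link_dist:
                    cands.append((d, int(slab)))
            if cands:
                cands.sort()
                if len(cands) > 1 and math.isclose(cands[0][0], cands[1][0]):
                    logger.info(
                        "field %d: equidistant spindle candidates %s; taking lowest label",
                        field_index,
                        [c[1] for c in cands[:2]],
                    )
                spindle_label = cands[0][1]
                assigned.add(spindle_label)
        records.append(
            CellRecord(
                cell_id=cid,
                field=field_index,
                klass="mitotic" if mitotic else "interphase",
                dapi_label=int(lab),
                spindle_label=spindle_label,
                centroid=(float(row["y"]), float(row["x"])),
            )
        )
        cid += 1
    unlinked = [int(l) for l in spin_props.index if l not in assigned]
    return records, unlinked


def measure_pla(
    pla_img: ProjectedImage | np.ndarray,
    cell: CellRecord,
    selection: str,
    dapi_masks: LabeledMask,
    spindle_masks: LabeledMask | None = None,
    channel: str = "TRITC",
) -> float:
    """Sum of PLA-channel pixel values within the selected cell mask.

    ``selection`` ∈ {nucleus, chromosomes, spindle, union}: nucleus and
    chromosomes both address the cell's DAPI mask (named per class), spindle
    addresses the linked spindle mask, union their union.  Requesting a
    spindle-bearing selection for a cell without one raises
    :class:`SelectionError`.
    """
    arr = pla_img.channel(channel) if isinstance(pla_img, ProjectedImage) else pla_img
    if selection in ("nucleus", "chromosomes"):
        mask = dapi_masks.region(cell.dapi_label)
    elif selection == "spindle":
        if cell.spindle_label is None or spindle_masks is None:
            raise SelectionError(
                f"cell {cell.cell_id} ({cell.klass}) has no spindle mask"
            )
        mask = spindle_masks.region(cell.spindle_label)
    elif selection == "union":
        mask = dapi_masks.region(cell.dapi_label)
        if cell.spindle_label is not None and spindle_masks is not None:
            mask = mask | spindle_masks.region(cell.spindle_label)
    else:
        raise SelectionError(f"unknown selection '{selection}'")
    return float(arr[mask].sum())


# ---- evaluation ----------------------------------------------------------


@dataclass
class Detection:
    """One detected object: category plus centroid in its field."""

    field: int
    category: str
    y: float
    x: float


@dataclass
class EvaluationResult:
    """Coverage/precision of detections vs ground truth (percent)."""

    coverage_pct: float
    precision_pct: float
    n_truth: int
    n_detections: int
    n_matched: int
    per_class: dict[str, dict[str, int]]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "EvaluationResult":
        return cls(**d)


def detections_from_records(
    records: Sequence[CellRecord],
    spindle_masks_by_field: Mapping[int, LabeledMask],
) -> list[Detection]:
    """Map classified cells and spindle masks to evaluable detections."""
    dets = [
        Detection(
            r.field,
            "interphase_nucleus" if r.klass == "interphase" else "mitotic_chromosomes",
            r.centroid[0],
            r.centroid[1],
        )
        for r in records
    ]
    for f, sm in spindle_masks_by_field.items():
        for _, row in sm.props.iterrows():
            dets.append(Detection(f, "spindle", float(row["y"]), float(row["x"])))
    return dets


def evaluate_segmentation(
    detections: Sequence[Detection],
    truth: GroundTruthScene,
    match_rule: str = "centroid_in_mask",
) -> EvaluationResult:
    """Match detections to truth objects and compute coverage/precision.

    Default rule: a detection may match a truth object of the same class in
    the same field iff the detection centroid lies inside the truth shape;
    candidate pairs are assigned one-to-one greedily by centroid distance.
    coverage = 100·matched/truth, precision = 100·matched/detections.
    """
    if match_rule != "centroid_in_mask":
        raise ValueError(f"unknown match rule '{match_rule}'")
    per_class = {
        c: {"matched": 0, "missed": 0, "spurious": 0} for c in OBJECT_CLASSES
    }
    n_matched = 0
    for klass in OBJECT_CLASSES:
        t_objs = [o for o in truth.objects if o.klass == klass]
        d_objs = [d for d in detections if d.category == klass]
        pairs = []
        for di, d in enumerate(d_objs):
            for ti, o in enumerate(t_objs):
                if o.field != d.field or not o.contains(d.y, d.x):
                    continue
                cy, cx = o.centroid
                pairs.append((math.hypot(d.y - cy, d.x - cx), di, ti))
        pairs.sort()
        used_d: set[int] = set()
        used_t: set[int] = set()
        m = 0
        for _, di, ti in pairs:
            if di in used_d or ti in used_t:
                continue
            used_d.add(di)
            used_t.add(ti)
            m += 1
        per_class[klass]["matched"] = m
        per_class[klass]["missed"] = len(t_objs) - m
        per_class[klass]["spurious"] = len(d_objs) - m
        n_matched += m
    n_truth = len(truth.objects)
    n_det = len(detections)
    coverage = 100.0 * n_matched / n_truth if n_truth else 100.0
    precision = 100.0 * n_matched / n_det if n_det else 100.0
    return EvaluationResult(
        coverage_pct=coverage,
        precision_pct=precision,
        n_truth=n_truth,
        n_detections=n_det,
        n_matched=n_matched,
        per_class=per_class,
    )


def summarize_evaluations(results: Sequence[EvaluationResult]) -> dict:
    cov = np.array([r.coverage_pct for r in results])
    prec = np.array([r.precision_pct for r in results])
    return {
        "coverage_pct": float(cov.mean()),
        "coverage_sd": float(cov.std(ddof=1)) if len(cov) > 1 else 0.0,
        "precision_pct": float(prec.mean()),
        "precision_sd": float(prec.std(ddof=1)) if len(prec) > 1 else 0.0,
        "n_replicates": len(results),
    }


# ---- whole-stack analysis ------------------------------------------------


@dataclass
class ImagingParams:
    """Bundle of the imaging-leg processing parameters."""

    background_method: str = "percentile"
    # 85th percentile rather than the median: with a dark-dominated PLA
    # channel this over-subtracts by ~1 noise-sd, and the zero clip then
    # removes most of the residual-noise floor that would otherwise bias
    # small per-cell sum intensities upward
    background_q: float = 85.0
    background_value: float = 0.0
    segmentation: SegmentationParams = field(default_factory=default_segmentation_params)
    classify: ClassifyParams = field(default_factory=ClassifyParams)
    mitotic_selection: str = "union"
    interphase_selection: str = "nucleus"
    measure_on_subtracted: bool = True


@dataclass
class StackAnalysis:
    """Per-field analysis of an acquisition: records and detections."""

    records: list[CellRecord]
    detections: list[Detection]
    n_fields: int

    def mitotic_sums(self) -> list[float]:
        return [
            r.pla_sum_intensity
            for r in self.records
            if r.klass == "mitotic" and r.pla_sum_intensity is not None
        ]


def analyze_field(
    stack: np.ndarray, field_index: int, params: ImagingParams
) -> tuple[list[CellRecord], LabeledMask, LabeledMask, ProjectedImage]:
    """Project, subtract, segment, classify and quantify one field."""
    mip = max_intensity_projection(stack, field_index)
    sub = subtract_background(
        mip,
        method=params.background_method,
        q=params.background_q,
        value=params.background_value,
    )
    dapi = segment_dapi(sub, params.segmentation)
    spin = segment_category(sub, params.segmentation, "spindle")
    records, _ = classify_cells(dapi, spin, params.classify, field_index=field_index)
    measured = sub if params.measure_on_subtracted else mip
    for r in records:
        sel = (
            params.mitotic_selection
            if r.klass == "mitotic"
            else params.interphase_selection
        )
        r.pla_sum_intensity = measure_pla(measured, r, sel, dapi, spin)
    return records, dapi, spin, sub


def analyze_stack(stack: np.ndarray, params: ImagingParams | None = None) -> StackAnalysis:
    """Run the imaging leg over every field of an acquisition stack."""
    if params is None:
        params = ImagingParams()
    all_records: list[CellRecord] = []
    spindle_by_field: dict[int, LabeledMask] = {}
    for f in range(stack.shape[0]):
        records, _dapi, spin, _sub = analyze_field(stack, f, params)
        all_records.extend(records)
        spindle_by_field[f] = spin
    dets = detections_from_records(all_records, spindle_by_field)
    return StackAnalysis(records=all_records, detections=dets, n_fields=stack.shape[0])


def records_to_frame(records: Sequence[CellRecord], condition: str = "") -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cell_id": r.cell_id,
                "field": r.field,
                "condition": condition,
                "class": r.klass,
                "centroid_y": r.centroid[0],
                "centroid_x": r.centroid[1],
                "pla_sum_intensity": r.pla_sum_intensity,
            }
            for r in records
        ]
    )


# ---- condition comparison ------------------------------------------------


@dataclass
class ComparisonResult:
    """Two-sided Mann-Whitney comparison of per-cell PLA sum intensities."""

    u_statistic: float
    p_value: float
    n_ctr: int
    n_ipz: int
    median_ctr: float
    median_ipz: float
    method: str

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ComparisonResult":
        return cls(**d)


def _mwu_enumeration(ctr: np.ndarray, ipz: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney by full enumeration of rank assignments.

    Works with ties (midranks).  Feasible only for small pooled sizes; used
    both as the small-sample implementation and as the oracle the
    large-sample path is tested against.
    """
    n1, n2 = len(ctr), len(ipz)
    pooled = np.concatenate([ctr, ipz])
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    dev = abs(u_obs - mu)
    total = 0
    extreme = 0
    for idx in combinations(range(n1 + n2), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0
        total += 1
        if abs(u - mu) >= dev - 1e-12:
            extreme += 1
    return float(u_obs), extreme / total


def compare_conditions(
    ctr: Sequence[float], ipz: Sequence[float]
) -> ComparisonResult:
    """Two-sided Mann-Whitney U test between the two condition samples.

    The exact null distribution is used whenever it is affordable: full
    enumeration (tie-safe) for small pooled samples, the tie-free exact
    recurrence when the smaller sample has at most 8 observations, and the
    tie-corrected normal approximation otherwise.
    """
    a = np.asarray(list(ctr), dtype=float)
    b = np.asarray(list(ipz), dtype=float)
    if len(a) < 1 or len(b) < 1:
        raise ValueError("both condition samples must be non-empty")
    n1, n2 = len(a), len(b)
    has_ties = len(np.unique(np.concatenate([a, b]))) < n1 + n2
    if math.comb(n1 + n2, n1) <= 20000:
        u, p = _mwu_enumeration(a, b)
        method = "exact_enumeration"
    elif min(n1, n2) <= 8 and not has_ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        u, p = float(res.statistic), float(res.pvalue)
        method = "exact"
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        u, p = float(res.statistic), float(res.pvalue)
        method = "asymptotic"
    p = min(max(p, np.finfo(float).tiny), 1.0)
    return ComparisonResult(
        u_statistic=u,
        p_value=p,
        n_ctr=n1,
        n_ipz=n2,
        median_ctr=float(np.median(a)),
        median_ipz=float(np.median(b)),
        method=method,
    )


def significance_stars(p: float) -> str:
    """Figure-style significance annotation at 0.05/0.01/0.001/0.0001."""
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 5e-2:
        return "*"
    return "ns"


# --------------------------------------------------------------------------
# Section 3 — interactome analysis
# --------------------------------------------------------------------------


@dataclass
class ProteinGroupRow:
    """One parsed proteinGroups row."""

    group_id: str
    gene_names: tuple[str, ...]
    unique_peptides: int
    peptides: int
    msms_count: int
    only_by_site: bool
    reverse: bool
    contaminant: bool
    intensities: dict[str, float]


def parse_protein_groups(source) -> list[ProteinGroupRow]:
    """Parse a MaxQuant-dialect tab-separated proteinGroups table.

    ``source`` may be a path, a file-like object or a DataFrame.  Flags are
    encoded as "+"/empty; multi-gene association is a ";"-separated gene
    name field; intensity columns are those prefixed "Intensity ".
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    for col in REQUIRED_PG_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"required column missing: '{col}'")
    int_cols = [c for c in df.columns if c.startswith("Intensity ")]
    rows: list[ProteinGroupRow] = []
    for i, rec in enumerate(df.to_dict("records")):
        counts = {}
        for col in ("Unique peptides", "Peptides", "MS/MS count"):
            try:
                counts[col] = int(float(rec[col]))
            except (TypeError, ValueError):
                raise ValueError(
                    f"row {i}: non-numeric value '{rec[col]}' in column '{col}'"
                ) from None
        genes = tuple(
            g.strip() for g in str(rec["Gene names"]).split(";") if g.strip()
        )
        intensities = {}
        for c in int_cols:
            try:
                intensities[c[len("Intensity ") :]] = float(rec[c])
            except (TypeError, ValueError):
                raise ValueError(
                    f"row {i}: non-numeric intensity '{rec[c]}' in column '{c}'"
                ) from None
        rows.append(
            ProteinGroupRow(
                group_id=str(rec["Protein IDs"]),
                gene_names=genes,
                unique_peptides=counts["Unique peptides"],
                peptides=counts["Peptides"],
                msms_count=counts["MS/MS count"],
                only_by_site=str(rec["Only identified by site"]).strip() == "+",
                reverse=str(rec["Reverse"]).strip() == "+",
                contaminant=str(rec["Potential contaminant"]).strip() == "+",
                intensities=intensities,
            )
        )
    return rows


#: sequential confidence-filter rules, applied in this order.
FILTER_RULES: tuple[tuple[str, object], ...] = (
    ("contaminant", lambda r: r.contaminant),
    ("reverse", lambda r: r.reverse),
    ("unique_peptides_le0", lambda r: r.unique_peptides <= 0),
    ("peptides_le1", lambda r: r.peptides <= 1),
    ("only_by_site", lambda r: r.only_by_site),
    ("msms_lt3", lambda r: r.msms_count < 3),
    ("multi_gene", lambda r: len(r.gene_names) > 1),
)


@dataclass
class FilterReport:
    """Reconciled ledger of the sequential confidence filtering."""

    input_count: int
    removed: dict[str, int]
    marginal: dict[str, int]  # independent per-rule counts on the input
    survivor_count: int
    survivor_ids: list[str]

    def reconciles(self) -> bool:
        return self.input_count - sum(self.removed.values()) == self.survivor_count

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "FilterReport":
        return cls(**d)


def apply_confidence_filters(
    rows: Sequence[ProteinGroupRow],
) -> tuple[list[ProteinGroupRow], FilterReport]:
    """Sequentially remove low-confidence protein groups.

    Order: potential contaminants, reverse-decoy hits, zero unique peptides,
    at most one peptide, only-identified-by-site, fewer than 3 MS/MS
    spectra, ambiguous (multi-gene) association.  A row removed by an
    earlier rule is not counted again by later ones; marginal (independent)
    counts are also reported so the ledger reconciles both ways.
    """
    removed = {name: 0 for name, _ in FILTER_RULES}
    marginal = {
        name: sum(1 for r in rows if rule(r)) for name, rule in FILTER_RULES
    }
    survivors: list[ProteinGroupRow] = []
    for r in rows:
        for name, rule in FILTER_RULES:
            if rule(r):
                removed[name] += 1
                break
        else:
            survivors.append(r)
    report = FilterReport(
        input_count=len(rows),
        removed=removed,
        marginal=marginal,
        survivor_count=len(survivors),
        survivor_ids=[r.group_id for r in survivors],
    )
    assert report.reconciles()
    return survivors, report


@dataclass
class EnrichmentResult:
    """Per-group bait-vs-control enrichment statistics."""

    table: pd.DataFrame  # group_id, gene, log2fc, t, p, q, hit, n_imputed
    alpha: float
    imputation: dict
    skipped: list[str]

    def hits(self) -> pd.DataFrame:
        return self.table[self.table["hit"]]


def test_enrichment(
    survivors: Sequence[ProteinGroupRow],
    bait_samples: Sequence[str],
    control_samples: Sequence[str],
    alpha: float = 0.05,
    impute: bool = True,
    imputation_shift: float = 1.8,
    imputation_width: float = 0.3,
    seed: int = 0,
) -> EnrichmentResult:
    """Welch test of bait vs control log2 intensities per protein group.

    Intensities are log2-transformed; zeros are treated as missing.  When
    imputation is enabled, missing values are drawn from a normal
    distribution down-shifted by ``imputation_shift``·sd and narrowed to
    ``imputation_width``·sd of the observed log2 intensities (the standard
    label-free missing-not-at-random workflow), with a seeded generator.  A
    group is a hit iff its two-sided p-value is below ``alpha`` AND its mean
    bait log2 intensity exceeds the control mean.  In complete-case mode,
    groups with fewer than 2 valid values on either side are skipped with a
    warning.
    """
    if len(bait_samples) < 2 or len(control_samples) < 2:
        raise ValueError("need >= 2 replicates per side")
    n = len(survivors)
    B = np.full((n, len(bait_samples)), np.nan)
    C = np.full((n, len(control_samples)), np.nan)
    for i, r in enumerate(survivors):
        for j, s in enumerate(bait_samples):
            v = r.intensities.get(s, 0.0)
            if v > 0:
                B[i, j] = math.log2(v)
        for j, s in enumerate(control_samples):
            v = r.intensities.get(s, 0.0)
            if v > 0:
                C[i, j] = math.log2(v)

    n_imp_b = np.isnan(B).sum(axis=1)
    n_imp_c = np.isnan(C).sum(axis=1)
    imput_meta: dict = {"enabled": impute, "seed": seed}
    skipped: list[str] = []
    if impute:
        obs = np.concatenate([B[np.isfinite(B)], C[np.isfinite(C)]])
        if obs.size:
            mu, sd = float(obs.mean()), float(obs.std(ddof=1)) if obs.size > 1 else 0.0
            rng = np.random.default_rng([seed, 5])
            for M in (B, C):
                miss = np.isnan(M)
                M[miss] = rng.normal(
                    mu - imputation_shift * sd, imputation_width * sd, miss.sum()
                )
            imput_meta.update(
                shift=imputation_shift,
                width=imputation_width,
                observed_mean=mu,
                observed_sd=sd,
                n_imputed=int(n_imp_b.sum() + n_imp_c.sum()),
            )

    rows = []
    for i, r in enumerate(survivors):
        b, c = B[i][np.isfinite(B[i])], C[i][np.isfinite(C[i])]
        if len(b) < 2 or len(c) < 2:
            logger.warning("group %s skipped: <2 valid values per side", r.group_id)
            skipped.append(r.group_id)
            continue
        log2fc = float(b.mean() - c.mean())
        t, p = stats.ttest_ind(b, c, equal_var=False)
        if not np.isfinite(p):  # zero variance on both sides
            t, p = 0.0, 1.0
        p = min(max(float(p), np.finfo(float).tiny), 1.0)
        rows.append(
            {
                "group_id": r.group_id,
                "gene": r.gene_names[0] if r.gene_names else "",
                "log2fc": log2fc,
                "t": float(t),
                "p": p,
                "hit": bool(p < alpha and log2fc > 0),
                "n_imputed_bait": int(n_imp_b[i]),
                "n_imputed_control": int(n_imp_c[i]),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "group_id",
            "gene",
            "log2fc",
            "t",
            "p",
            "hit",
            "n_imputed_bait",
            "n_imputed_control",
        ],
    )
    if len(table):
        table["q"] = multipletests(table["p"], method="fdr_bh")[1]
    else:
        table["q"] = pd.Series(dtype=float)
    return EnrichmentResult(table=table, alpha=alpha, imputation=imput_meta, skipped=skipped)


test_enrichment.__test__ = False  # statistical routine, not a pytest case


@dataclass
class CategorySummary:
    """Phenotype tallies and percentages over the annotated hits."""

    total_hits: int
    annotated_count: int
    unannotated_count: int
    counts: dict[str, int]
    percentages: dict[str, float | None]  # unrounded; None when undefined
    display: dict[str, str]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CategorySummary":
        return cls(**d)


def annotate_phenotypes(
    hit_genes: Iterable[str], annotation: pd.DataFrame
) -> CategorySummary:
    """Cross-tabulate hit genes against a gene→phenotype annotation table.

    Hits without an annotation entry count as unannotated; percentages are
    computed over the annotated subset only, reported unrounded alongside a
    two-decimal display string.  Conflicting duplicate annotations for one
    gene raise an error listing the genes.
    """
    if not {"gene", "category"} <= set(annotation.columns):
        raise ValueError("annotation table needs 'gene' and 'category' columns")
    bad = set(annotation["category"]) - set(PHENOTYPE_CATEGORIES)
    if bad:
        raise ValueError(f"unknown phenotype categories: {sorted(bad)}")
    conflicts = (
        annotation.drop_duplicates()
        .groupby("gene")["category"]
        .nunique()
        .pipe(lambda s: sorted(s[s > 1].index))
    )
    if conflicts:
        raise ValueError(f"conflicting annotations for genes: {conflicts}")
    mapping = dict(zip(annotation["gene"], annotation["category"]))
    hits = list(hit_genes)
    counts = {c: 0 for c in PHENOTYPE_CATEGORIES}
    annotated = 0
    for g in hits:
        cat = mapping.get(g)
        if cat is None:
            continue
        annotated += 1
        counts[cat] += 1
    percentages: dict[str, float | None] = {}
    display: dict[str, str] = {}
    for c in PHENOTYPE_CATEGORIES:
        if annotated:
            pct = 100.0 * counts[c] / annotated
            percentages[c] = pct
            display[c] = f"{pct:.2f}"
        else:
            percentages[c] = None
            display[c] = "n/a"
    return CategorySummary(
        total_hits=len(hits),
        annotated_count=annotated,
        unannotated_count=len(hits) - annotated,
        counts=counts,
        percentages=percentages,
        display=display,
    )


# --------------------------------------------------------------------------
# Section 4 — pipeline orchestration, manifest, reporting
# --------------------------------------------------------------------------


# nested dataclass field types are stored as strings under
# `from __future__ import annotations`; resolve them explicitly here
_NESTED_TYPES: dict[str, type] = {}


def _dataclass_from_dict(cls, d: Mapping):
    """Strict dataclass construction: unknown keys are rejected, nested
    dataclasses recursed into, lists coerced to tuples where declared."""
    fieldmap = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(d) - set(fieldmap)
    if unknown:
        raise ValueError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    for k, v in d.items():
        f = fieldmap[k]
        tname = f.type if isinstance(f.type, str) else getattr(f.type, "__name__", "")
        tp = _NESTED_TYPES.get(tname.split("[")[0].strip())
        if cls is SegmentationParams and k == "categories" and isinstance(v, Mapping):
            kwargs[k] = {
                name: _dataclass_from_dict(CategoryParams, cp) for name, cp in v.items()
            }
        elif tp is not None and isinstance(v, Mapping):
            kwargs[k] = _dataclass_from_dict(tp, v)
        elif isinstance(v, list):
            default = f.default
            if default is dataclasses.MISSING and f.default_factory is not dataclasses.MISSING:  # type: ignore[misc]
                default = f.default_factory()  # type: ignore[misc]
            kwargs[k] = tuple(v) if isinstance(default, tuple) else v
        else:
            kwargs[k] = v
    return cls(**kwargs)


@dataclass
class StageToggles:
    simulation: bool = True
    imaging: bool = True
    interactome: bool = True


@dataclass
class InteractomeConfig:
    alpha: float = 0.05
    impute: bool = True
    imputation_shift: float = 1.8
    imputation_width: float = 0.3
    bait_prefix: str = "IP"
    control_prefix: str = "IgG"


@dataclass
class PipelineConfig:
    """Schema-validated configuration of the full three-step pipeline."""

    rng_seed: int = 1
    output_dir: str = "mitopla_out"
    log_level: str = "INFO"
    save_stacks: bool = False
    stages: StageToggles = field(default_factory=StageToggles)
    scene: SceneParams = field(
        default_factory=lambda: SceneParams(field_grid_count=15, mitotic_fraction=0.5)
    )
    imaging: ImagingParams = field(default_factory=ImagingParams)
    protein_groups: ProteinGroupFixtureParams = field(
        default_factory=ProteinGroupFixtureParams
    )
    interactome: InteractomeConfig = field(default_factory=InteractomeConfig)

    def to_dict(self) -> dict:
        # JSON round trip normalises tuples to lists for YAML/JSON output
        return json.loads(json.dumps(dataclasses.asdict(self)))

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        cfg = _dataclass_from_dict(cls, d)
        cfg.scene.validate()
        cfg.protein_groups.validate()
        cfg.imaging.segmentation.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


_NESTED_TYPES.update(
    SceneParams=SceneParams,
    ProteinGroupFixtureParams=ProteinGroupFixtureParams,
    SegmentationParams=SegmentationParams,
    CategoryParams=CategoryParams,
    ClassifyParams=ClassifyParams,
    ImagingParams=ImagingParams,
    StageToggles=StageToggles,
    InteractomeConfig=InteractomeConfig,
)


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    config_hash: str
    rng_seed: int
    package_version: str
    created_at: str
    stages: dict[str, str]
    outputs: dict[str, str]  # relative path -> sha256

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the enabled stages (simulate → imaging → interactome).

    Writes all declared outputs plus a manifest under ``config.output_dir``.
    A stage failure leaves the completed stages' outputs in place, records
    the failure in the manifest, and raises :class:`PipelineStageError`.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    configure_logging(config.log_level, outdir / "pipeline.log")
    cfg_json = json.dumps(config.to_dict(), sort_keys=True)
    manifest = RunManifest(
        config_hash=hashlib.sha256(cfg_json.encode()).hexdigest(),
        rng_seed=config.rng_seed,
        package_version=__import__("mitopla").__version__,
        created_at=datetime.now(timezone.utc).isoformat(),
        stages={},
        outputs={},
    )
    results: dict = {}
    state: dict = {}

    def register(path: Path) -> None:
        manifest.outputs[str(path.relative_to(outdir))] = _sha256(path)

    stage_fns = []
    if config.stages.simulation:
        stage_fns.append(("simulation", _stage_simulation))
    if config.stages.imaging:
        stage_fns.append(("imaging", _stage_imaging))
    if config.stages.interactome:
        stage_fns.append(("interactome", _stage_interactome))

    for name, fn in stage_fns:
        logger.info("running stage: %s", name)
        try:
            fn(config, outdir, state, results, register)
            manifest.stages[name] = "ok"
        except Exception as exc:  # record, persist, re-raise
            manifest.stages[name] = f"failed: {exc}"
            manifest.save(outdir / "manifest.json")
            raise PipelineStageError(name, str(exc)) from exc

    write_report(manifest, results, outdir)
    for p in sorted(outdir.iterdir()):
        if p.is_file() and p.name not in ("manifest.json", "pipeline.log"):
            register(p)
    manifest.save(outdir / "manifest.json")
    return manifest


def _stage_simulation(config, outdir, state, results, register) -> None:
    base = config.scene
    for cond, seed_off in (("CTR", 0), ("IPZ", 1)):
        params = dataclasses.replace(
            base, condition=cond, rng_seed=config.rng_seed + seed_off
        )
        scene, stack = generate_scene(params)
        state[f"scene_{cond}"] = scene
        state[f"stack_{cond}"] = stack
        scene.save(outdir / f"scene_{cond}.json")
        if config.save_stacks:
            write_stack(outdir / f"stack_{cond}.tif", stack, params.pixel_size_um)
    pg_params = dataclasses.replace(
        config.protein_groups, rng_seed=config.rng_seed + 2
    )
    table, truth = generate_protein_groups(pg_params)
    write_protein_groups(table, outdir / "proteinGroups.txt")
    truth.to_csv(outdir / "proteinGroups_truth.tsv", sep="\t", index=False)
    ann = generate_annotation_table(
        table["Gene names"].str.split(";").str[0], rng_seed=config.rng_seed + 3
    )
    ann.to_csv(outdir / "annotation.tsv", sep="\t", index=False)
    state["pg_table"] = table
    state["annotation"] = ann


def _stage_imaging(config, outdir, state, results, register) -> None:
    frames = []
    evals = {}
    sums = {}
    for cond in ("CTR", "IPZ"):
        stack = state.get(f"stack_{cond}")
        scene = state.get(f"scene_{cond}")
        if stack is None:
            raise RuntimeError(f"no simulated stack for condition {cond}")
        analysis = analyze_stack(stack, config.imaging)
        frames.append(records_to_frame(analysis.records, condition=cond))
        evals[cond] = evaluate_segmentation(analysis.detections, scene)
        sums[cond] = analysis.mitotic_sums()
    cells = pd.concat(frames, ignore_index=True)
    cells.to_csv(outdir / "per_cell_intensities.tsv", sep="\t", index=False)
    comparison = compare_conditions(sums["CTR"], sums["IPZ"])
    results["evaluation"] = {c: e.to_dict() for c, e in evals.items()}
    results["comparison"] = comparison.to_dict()
    (outdir / "comparison.json").write_text(json.dumps(comparison.to_dict(), indent=2))
    (outdir / "evaluation.json").write_text(
        json.dumps(results["evaluation"], indent=2)
    )


def _stage_interactome(config, outdir, state, results, register) -> None:
    table = state.get("pg_table")
    if table is None:
        table = pd.read_csv(outdir / "proteinGroups.txt", sep="\t", keep_default_na=False)
    rows = parse_protein_groups(table)
    survivors, report = apply_confidence_filters(rows)
    nrep = config.protein_groups.replicates
    enr = test_enrichment(
        survivors,
        bait_sample_names(nrep),
        control_sample_names(nrep),
        alpha=config.interactome.alpha,
        impute=config.interactome.impute,
        imputation_shift=config.interactome.imputation_shift,
        imputation_width=config.interactome.imputation_width,
        seed=config.rng_seed + 4,
    )
    enr.table.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    ann = state.get("annotation")
    if ann is None:
        ann = pd.read_csv(outdir / "annotation.tsv", sep="\t")
    summary = annotate_phenotypes(enr.hits()["gene"], ann)
    results["filter_report"] = report.to_dict()
    results["category_summary"] = summary.to_dict()
    results["n_hits"] = int(enr.table["hit"].sum())
    (outdir / "filter_report.json").write_text(json.dumps(report.to_dict(), indent=2))
    (outdir / "category_summary.json").write_text(
        json.dumps(summary.to_dict(), indent=2)
    )


def write_report(manifest: RunManifest, results: Mapping, outdir: str | Path) -> None:
    """Write the machine-readable report plus a human-readable summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = {
        "config_hash": manifest.config_hash,
        "sections": {
            "evaluation": results.get("evaluation"),
            "comparison": results.get("comparison"),
            "filter_report": results.get("filter_report"),
            "category_summary": results.get("category_summary"),
        },
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    lines = ["mitopla pipeline report", "=" * 23, ""]
    comp = results.get("comparison")
    if comp:
        stars = significance_stars(comp["p_value"])
        lines += [
            "PLA condition comparison (per-cell sum intensity, a.u.):",
            f"  CTR median {comp['median_ctr']:.0f} (n={comp['n_ctr']}) vs "
            f"IPZ median {comp['median_ipz']:.0f} (n={comp['n_ipz']})",
            f"  Mann-Whitney U={comp['u_statistic']:.1f}, "
            f"two-sided p={comp['p_value']:.3g} {stars}",
            "",
        ]
    ev = results.get("evaluation")
    if ev:
        for cond, e in ev.items():
            lines.append(
                f"Segmentation vs truth [{cond}]: coverage "
                f"{e['coverage_pct']:.1f}%, precision {e['precision_pct']:.1f}%"
            )
        lines.append("")
    fr = results.get("filter_report")
    if fr:
        lines.append(
            f"Confidence filter: {fr['input_count']} groups in, "
            f"{fr['survivor_count']} survive "
            f"(removed: {fr['removed']})"
        )
    cs = results.get("category_summary")
    if cs:
        lines.append(
            f"Phenotype annotation: {cs['annotated_count']}/{cs['total_hits']} "
            f"hits annotated; {cs['display']}"
        )
    (outdir / "report.txt").write_text("\n".join(lines) + "\n")


def load_report(path: str | Path) -> dict:
    """Reload a report; result sections reconstruct to their dataclasses."""
    report = json.loads(Path(path).read_text())
    out = dict(report)
    secs = report.get("sections", {})
    parsed = {}
    if secs.get("comparison"):
        parsed["comparison"] = ComparisonResult.from_dict(secs["comparison"])
    if secs.get("filter_report"):
        parsed["filter_report"] = FilterReport.from_dict(secs["filter_report"])
    if secs.get("category_summary"):
        parsed["category_summary"] = CategorySummary.from_dict(secs["category_summary"])
    if secs.get("evaluation"):
        parsed["evaluation"] = {
            c: EvaluationResult.from_dict(e) for c, e in secs["evaluation"].items()
        }
    out["parsed"] = parsed
    return out
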