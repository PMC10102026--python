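"""Seeded synthetic inputs mirroring the emulated experimental design.

Every generator is a pure function of its parameters and seed and returns
ground truth alongside the data.  Structural constants (20 outgrowths and 16
pool-and-split controls per condition, 35% high-state penetrance with a 10%
background rate, the 100–400 µm² nuclear gate, 5-photon spot threshold,
0.142 µm pixels) mirror the experimental design; distributional choices (lognormal
noise, Gaussian spots, Poisson photons) are generic stand-ins.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

try:  # analytic area/perimeter of multi-lobed outgrowths
    from shapely.geometry import Point
    from shapely.ops import unary_union
    HAVE_SHAPELY = True
except ImportError:  # pragma: no cover
    HAVE_SHAPELY = False

from .freqmatch import ExpressionMatrix
from .transport import TRANSCRIPT_MAP

__all__ = [
    "CohortSpec",
    "gen_expression_cohort",
    "gen_outgrowth_masks",
    "gen_pla_image",
    "gen_nc_cells",
    "gen_model_profiles",
    "PIXEL_SIZE_UM",
]

#: default pixel size, µm per px (confocal step size used in the experiments)
PIXEL_SIZE_UM = 0.142


@dataclass
class CohortSpec:
    """Parameters of the synthetic single-outgrowth expression cohort."""

    n_genes: int = 1000
    n_biological: int = 20
    n_poolsplit: int = 16
    frac_heterogeneous: float = 0.05   # two-state genes in both conditions
    n_frequency_matched: int = 30      # AP-responsive two-state genes
    p_high: float = 0.35               # plus-AP high-state frequency
    p_background: float = 0.10         # minus-AP background high-state rate
    log2_fc_high: float = 2.0
    sd_biological: float = 0.2         # log2 units
    sd_technical: float = 0.15
    dropout: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.p_high <= 1 or not 0 <= self.p_background <= 1:
            raise ValueError("state probabilities must be in [0, 1]")
        if self.sd_biological <= 0 or self.sd_technical <= 0:
            raise ValueError("noise scales must be > 0")
        if self.frac_heterogeneous < 0 or \
                self.frac_heterogeneous * self.n_genes + self.n_frequency_matched > self.n_genes:
            raise ValueError("impossible gene-class fractions")


def gen_expression_cohort(spec: CohortSpec) -> tuple[ExpressionMatrix, dict]:
    """Two-condition cohort of 10-cell outgrowth profiles with controls.

    Gene classes: ``null`` genes share one lognormal distribution everywhere;
    ``heterogeneous`` genes occupy a two-state mixture among biological
    samples in both conditions; ``frequency_matched`` genes occupy the high
    state in each plus-AP outgrowth with probability ``p_high`` and in each
    minus-AP outgrowth at the background rate.  Pool-and-split samples carry
    technical noise around the condition mean.
    """
    rng = np.random.default_rng(spec.seed)
    n_het = int(round(spec.frac_heterogeneous * spec.n_genes))
    n_fm = spec.n_frequency_matched
    labels = np.array(
        ["frequency_matched"] * n_fm + ["heterogeneous"] * n_het
        + ["null"] * (spec.n_genes - n_fm - n_het)
    )
    genes = [f"G{i:05d}" for i in range(spec.n_genes)]
    base = rng.normal(8.0, 1.5, spec.n_genes)

    cols, cond_meta, type_meta = [], [], []
    for cond in ("minusAP", "plusAP"):
        for j in range(spec.n_biological):
            cols.append(f"{cond}_bio{j:02d}"); cond_meta.append(cond); type_meta.append("biological")
        for j in range(spec.n_poolsplit):
            cols.append(f"{cond}_ps{j:02d}"); cond_meta.append(cond); type_meta.append("poolsplit")

    values = np.empty((spec.n_genes, len(cols)))
    states = {}  # gene -> {condition: bool array of high states}
    for gi in range(spec.n_genes):
        lab = labels[gi]
        row = {}
        for cond in ("minusAP", "plusAP"):
            if lab == "null":
                p_hi, fc = 0.0, 0.0
            elif lab == "heterogeneous":
                p_hi, fc = 0.5, spec.log2_fc_high
            else:  # frequency_matched
                p_hi = spec.p_high if cond == "plusAP" else spec.p_background
                fc = spec.log2_fc_high
            hi = rng.random(spec.n_biological) < p_hi
            bio = base[gi] + hi * fc + rng.normal(0, spec.sd_biological, spec.n_biological)
            # pool-and-split: technical noise around the condition mean in
            # linear intensity space (a pooled lysate averages cell states)
            pool_mean = np.log2((1 - p_hi) * 2.0 ** base[gi] + p_hi * 2.0 ** (base[gi] + fc))
            ps = pool_mean + rng.normal(0, spec.sd_technical, spec.n_poolsplit)
            row[cond] = (bio, ps, hi)
        values[gi] = np.concatenate([row["minusAP"][0], row["minusAP"][1],
                                     row["plusAP"][0], row["plusAP"][1]])
        if lab != "null":
            states[genes[gi]] = {
                "minusAP": row["minusAP"][2].tolist(),
                "plusAP": row["plusAP"][2].tolist(),
            }

    df = pd.DataFrame(values, index=genes, columns=cols)
    samples = pd.DataFrame(
        {"condition": cond_meta, "sample_type": type_meta}, index=cols)
    detected = pd.DataFrame(
        rng.random(df.shape) >= spec.dropout, index=genes, columns=cols)
    truth = {
        "spec": asdict(spec),
        "labels": dict(zip(genes, labels.tolist())),
        "high_states": states,
    }
    return ExpressionMatrix(df, samples, detected), truth


def _rasterize_discs(centers, radius, shape):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    mask = np.zeros(shape, bool)
    for cy, cx in centers:
        mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2
    return mask


def gen_outgrowth_masks(n: int, radius_range=(20.0, 45.0), lobe_counts=(1, 2, 3),
                        seed: int = 0, pixel_size: float = 1.0):
    """Labelled masks of discs and multi-lobed disc unions.

    Lobe centers sit on a ring of half the lobe radius, so adjacent lobes
    overlap; the analytic circularity of each generated union (from exact
    geometry) is recorded as ground truth.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    tile = 160
    cols = int(np.ceil(np.sqrt(n)))
    rows = int(np.ceil(n / cols))
    label_img = np.zeros((rows * tile, cols * tile), dtype=np.int32)
    truth = []
    for i in range(n):
        r = rng.uniform(*radius_range)
        lobes = int(rng.choice(lobe_counts))
        cy = (i // cols) * tile + tile / 2
        cx = (i % cols) * tile + tile / 2
        if lobes == 1:
            centers = [(cy, cx)]
        else:
            ring = r * 0.75
            angles = 2 * np.pi * np.arange(lobes) / lobes + rng.uniform(0, 2 * np.pi)
            centers = [(cy + ring * np.sin(a), cx + ring * np.cos(a)) for a in angles]
        mask = _rasterize_discs(centers, r, label_img.shape)
        label_img[mask] = i + 1
        rec = {"label": i + 1, "lobes": lobes, "radius_px": float(r)}
        if HAVE_SHAPELY:
            poly = unary_union([Point(cx_, cy_).buffer(r, quad_segs=256)
                                for cy_, cx_ in centers])
            rec["true_area_px"] = float(poly.area)
            rec["true_perimeter_px"] = float(poly.length)
            rec["true_circularity"] = float(4 * np.pi * poly.area / poly.length ** 2)
        truth.append(rec)
    return label_img, {"pixel_size_um": pixel_size, "objects": truth}


def gen_pla_image(n_nuclei: int = 9, spots_per_cell=5, peak_photons: float = 25.0,
                  background_rate: float = 0.2, seed: int = 0,
                  pixel_size: float = PIXEL_SIZE_UM, spot_sigma: float = 1.0,
                  threshold: float = 5.0):
    """Poisson photon-count image with Gaussian spots and elliptical nuclei.

    Nuclear areas span the 100–400 µm² analysis gate, with the first and
    last nucleus deliberately outside it.  Spots are placed within each
    nucleus's neighbourhood; overlapping spots closer than 2σ are flagged.
    The generator validates that the filtered background cannot reach the
    spot threshold.
    """
    rng = np.random.default_rng(seed)
    cols = int(np.ceil(np.sqrt(n_nuclei)))
    rows = int(np.ceil(n_nuclei / cols))
    tile = 220  # large enough that even the over-gate nucleus fits
    shape = (rows * tile, cols * tile)
    nuclei = np.zeros(shape, dtype=np.int32)
    lam = np.full(shape, background_rate, dtype=float)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]

    # areas in µm²: first below the gate, last above, the rest inside
    areas = np.linspace(150.0, 350.0, n_nuclei)
    if n_nuclei >= 2:
        areas[0], areas[-1] = 80.0, 450.0
    spots_truth = []
    for i in range(n_nuclei):
        cy = (i // cols) * tile + tile / 2
        cx = (i % cols) * tile + tile / 2
        area_px = areas[i] / pixel_size ** 2
        ecc = rng.uniform(0.7, 0.95)
        a = np.sqrt(area_px / (np.pi * ecc))
        b = area_px / (np.pi * a)
        nuclei[((yy - cy) / a) ** 2 + ((xx - cx) / b) ** 2 <= 1.0] = i + 1

        n_spots = spots_per_cell if np.isscalar(spots_per_cell) else int(rng.choice(spots_per_cell))
        placed = []
        for _ in range(n_spots):
            # rejection-sample so spots stay resolvable after LoG filtering
            for _attempt in range(200):
                sy = cy + rng.uniform(-tile / 2 + 12, tile / 2 - 12)
                sx = cx + rng.uniform(-tile / 2 + 12, tile / 2 - 12)
                if all((sy - py) ** 2 + (sx - px) ** 2 >= (8 * spot_sigma) ** 2
                       for py, px in placed):
                    break
            close = any((sy - py) ** 2 + (sx - px) ** 2 < (2 * spot_sigma) ** 2
                        for py, px in placed)
            placed.append((sy, sx))
            spots_truth.append({"nucleus": i + 1, "y": sy, "x": sx,
                                "overlapping": bool(close)})
            # stamp the Gaussian on a local window only
            w = int(np.ceil(8 * spot_sigma))
            y0, y1 = max(0, int(sy) - w), min(shape[0], int(sy) + w + 1)
            x0, x1 = max(0, int(sx) - w), min(shape[1], int(sx) + w + 1)
            wy, wx = np.mgrid[y0:y1, x0:x1]
            lam[y0:y1, x0:x1] += peak_photons * np.exp(
                -((wy - sy) ** 2 + (wx - sx) ** 2) / (2 * spot_sigma ** 2))

    image = rng.poisson(lam).astype(np.uint16)

    # background validation: the mean-zero LoG filter must not lift pure
    # Poisson background anywhere near the photon threshold
    bg = rng.poisson(background_rate, (256, 256)).astype(float)
    resp = -ndi.gaussian_laplace(bg, sigma=spot_sigma, truncate=7.0)
    if resp.max() > 0.8 * threshold:
        raise ValueError(
            f"background rate {background_rate} too high: filtered background "
            f"reaches {resp.max():.2f} of the {threshold}-photon threshold")

    truth = {
        "pixel_size_um": pixel_size,
        "areas_um2": areas.tolist(),
        "spots": spots_truth,
        "gate_um2": [100.0, 400.0],
    }
    return image, nuclei, truth


def gen_nc_cells(n_cells: int = 25, ratio_mean: float = 2.0, ratio_sigma: float = 0.0,
                 noise: float = 0.01, seed: int = 0, intensity: float = 200.0):
    """Paired-channel images of cells with known nuclear/cytoplasmic ratios.

    Each cell is a disc with a concentric nuclear disc; both channels
    realize the same per-cell true N/C ratio with independent multiplicative
    noise.  True ratios are lognormal around ``ratio_mean`` (``ratio_sigma``
    in log units; 0 gives identical ratios).
    """
    rng = np.random.default_rng(seed)
    cols = int(np.ceil(np.sqrt(n_cells)))
    rows = int(np.ceil(n_cells / cols))
    tile = 60
    shape = (rows * tile, cols * tile)
    cell_mask = np.zeros(shape, np.int32)
    nuc_mask = np.zeros(shape, np.int32)
    ch1 = np.zeros(shape, float)
    ch2 = np.zeros(shape, float)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    ratios = ratio_mean * np.exp(rng.normal(0.0, ratio_sigma, n_cells)) \
        if ratio_sigma > 0 else np.full(n_cells, float(ratio_mean))
    if np.any(ratios <= 0):
        raise ValueError("true ratios must be > 0")
    for i in range(n_cells):
        cy = (i // cols) * tile + tile / 2
        cx = (i % cols) * tile + tile / 2
        r_cell, r_nuc = 24, 11
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        cell = d2 <= r_cell ** 2
        nuc = d2 <= r_nuc ** 2
        cell_mask[cell] = i + 1
        nuc_mask[nuc] = i + 1
        for ch in (ch1, ch2):
            level = np.where(nuc, intensity * ratios[i], np.where(cell, intensity, 0.0))
            ch += level * (1.0 + rng.normal(0.0, noise, shape)) * (level > 0)
    truth = {"true_ratios": ratios.tolist()}
    return (ch1.astype(np.float64), ch2.astype(np.float64),
            nuc_mask, cell_mask, truth)


def gen_model_profiles(n_outgrowths: int = 20, dispersion: float = 0.25,
                       seed: int = 0, genes=None,
                       dispersion_overrides: dict | None = None) -> pd.DataFrame:
    """Per-outgrowth relative transcript levels for the transport genes.

    Levels are lognormal around 1 with the given log-dispersion; per-gene
    overrides allow making a single regulator (e.g. CSE1L) dominate the
    outgrowth-to-outgrowth variation.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    rng = np.random.default_rng(seed)
    genes = list(genes) if genes is not None else sorted(TRANSCRIPT_MAP)
    data = {}
    for g in genes:
        sd = (dispersion_overrides or {}).get(g, dispersion)
        data[g] = np.exp(rng.normal(0.0, sd, n_outgrowths)) if sd > 0 \
            else np.ones(n_outgrowths)
    return pd.DataFrame(data, index=[f"outgrowth{i:02d}" for i in range(n_outgrowths)])
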