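"""Synthetic cohorts with planted texture / expression / survival structure.

Every downstream stage of the pipeline is testable without any download:
the generator emits, per patient, an H&E-like slide image (tissue blobs on
a white background whose internal texture differs between the two marker
classes), a continuous marker value separated by class, survival times
whose hazard depends log-linearly on the marker class, independent
censoring, and a TPM-like expression matrix containing one planted gene
set correlated with the marker.

Texture mechanism: the tissue interior is a Gaussian random field whose
smoothing kernel width depends on the patient's class, scaled by
``texture_effect`` — wider kernels give smoother, lower-contrast texture,
which moves GLCM/GLRLM statistics directly without modeling histology.
Survival: exponential baseline parameterized by the median survival of the
low-marker class, proportional hazard exp(log_hazard_ratio) for the high
class, censoring by an independent exponential calibrated to the requested
overall censoring fraction.  Expression: signal genes equal the marker
plus Gaussian noise on a log2 latent scale, exponentiated to a TPM-like
positive scale.

Everything is reproducible from ``CohortConfig.seed`` alone; slides are
rendered lazily so large-n cohorts (for parameter-recovery simulations)
never materialize images.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, zoom
from scipy.optimize import brentq

from pathoscore.enrichment import GeneSet
from pathoscore.tiling import SOURCE_TILE_PX, SlideImage

logger = logging.getLogger(__name__)

# H&E-like palette endpoints (RGB): eosin pink stroma, hematoxylin purple.
PINK = np.array([230.0, 172.0, 208.0])
PURPLE = np.array([96.0, 64.0, 150.0])
BACKGROUND_LEVEL = 245
BASE_SIGMA = 1.6


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the seed cohort: 78 patients with both expression and
    slide data, roughly a third in the high-marker class, a high-vs-low
    hazard ratio of 1.9, ~20% censoring, and a marker dichotomization
    point of 4.2784 on the log2 scale.
    """

    n_patients: int = 78
    prevalence_high: float = 0.34
    texture_effect: float = 1.0
    marker_cutoff: float = 4.2784
    log_hazard_ratio: float = float(np.log(1.9))
    baseline_median_months: float = 14.0
    censor_rate: float = 0.2
    slide_px: int = 2048
    magnification: int = 20
    n_signal_genes: int = 30
    n_noise_genes: int = 470
    seed: int = 0
    tissue_fraction: float = 0.75
    marker_separation: float = 1.0   # class offset from the cutoff (log2 units)
    marker_sd: float = 0.5

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if not 0 < self.prevalence_high < 1:
            raise ValueError("prevalence_high must lie in (0, 1)")
        if self.texture_effect < 0:
            raise ValueError("texture_effect must be non-negative")
        if self.baseline_median_months <= 0:
            raise ValueError("baseline_median_months must be positive")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must lie in [0, 1)")
        if self.magnification not in SOURCE_TILE_PX:
            raise ValueError("magnification must be 20 or 40")
        if not 0 < self.tissue_fraction <= 1:
            raise ValueError("tissue_fraction must lie in (0, 1]")
        src = SOURCE_TILE_PX[self.magnification]
        n_tiles = (self.slide_px // src) ** 2
        if n_tiles < 10:
            raise ValueError(
                f"slide_px={self.slide_px} at {self.magnification}x holds only "
                f"{n_tiles} tiles; need >= 10")


@dataclass
class SyntheticPatient:
    patient_id: str
    true_class: int              # 1 = high marker
    marker_value: float          # log2-scale expression surrogate
    survival_months: float
    event: int
    covariates: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.survival_months <= 0:
            raise ValueError("survival_months must be positive")
        if self.event not in (0, 1):
            raise ValueError("event must be 0/1")


@dataclass
class Cohort:
    config: CohortConfig
    patients: list
    expression: pd.DataFrame     # genes x patients, TPM-like
    gene_sets: list              # planted signal set first, then decoys

    def clinical_table(self) -> pd.DataFrame:
        rows = []
        for p in self.patients:
            rows.append({"patient_id": p.patient_id, "class": p.true_class,
                         "marker": p.marker_value,
                         "time_months": p.survival_months, "event": p.event,
                         **p.covariates})
        return pd.DataFrame(rows)

    def labels(self) -> pd.Series:
        t = self.clinical_table().set_index("patient_id")
        return (t["marker"] > self.config.marker_cutoff).astype(int)

    def slides(self):
        """Lazily render one slide per patient."""
        for p in self.patients:
            yield render_slide(p, self.config)


def _censor_rate_solve(rates: np.ndarray, target: float) -> float:
    """Censoring hazard rc with E[P(C < T)] = target for exponential T, C."""
    f = lambda rc: np.mean(rc / (rc + rates)) - target
    hi = rates.max() * 1e3
    return brentq(f, 1e-12, hi)


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate the patients, expression matrix, and gene sets of a cohort.

    Slides are available from :meth:`Cohort.slides` / :func:`render_slide`.
    Fully deterministic given ``config``.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    n = config.n_patients
    # exact class counts at the configured prevalence, random positions
    n_high = int(round(config.prevalence_high * n))
    n_high = min(max(n_high, 1), n - 1)
    high = np.zeros(n, dtype=int)
    high[rng.choice(n, size=n_high, replace=False)] = 1
    marker = (config.marker_cutoff
              + np.where(high == 1, config.marker_separation,
                         -config.marker_separation)
              + rng.normal(0, config.marker_sd, n))
    base_rate = np.log(2) / config.baseline_median_months
    rates = base_rate * np.exp(config.log_hazard_ratio * high)
    t_event = rng.exponential(1.0 / rates)
    if config.censor_rate > 0:
        rc = _censor_rate_solve(rates, config.censor_rate)
        t_cens = rng.exponential(1.0 / rc, n)
    else:
        t_cens = np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    time = np.maximum(time, 1e-3)
    age = np.where(rng.random(n) < 0.44, "<=59", "60+")
    sex = np.where(rng.random(n) < 0.32, "female", "male")
    width = max(3, len(str(n)))
    patients = [
        SyntheticPatient(
            patient_id=f"P{i + 1:0{width}d}", true_class=int(high[i]),
            marker_value=float(marker[i]), survival_months=float(time[i]),
            event=int(event[i]),
            covariates={"age_group": str(age[i]), "sex": str(sex[i])})
        for i in range(n)
    ]
    expression = _expression_matrix(config, marker, [p.patient_id for p in patients])
    gene_sets = _gene_sets(config, expression.index)
    return Cohort(config, patients, expression, gene_sets)


def _expression_matrix(config: CohortConfig, marker: np.ndarray,
                       patient_ids: list) -> pd.DataFrame:
    rng = np.random.default_rng([config.seed, 2])
    n = len(patient_ids)
    rows, names = [], []
    for g in range(config.n_signal_genes):
        latent = marker + rng.normal(0, 0.7, n)
        rows.append(2.0 ** latent)
        names.append(f"SIG{g + 1:04d}")
    for g in range(config.n_noise_genes):
        offset = rng.normal(3.0, 0.5)
        latent = offset + rng.normal(0, 1.0, n)
        rows.append(2.0 ** latent)
        names.append(f"NOISE{g + 1:04d}")
    return pd.DataFrame(rows, index=pd.Index(names, name="gene"),
                        columns=patient_ids)


def _gene_sets(config: CohortConfig, gene_index, n_decoys: int = 9) -> list:
    rng = np.random.default_rng([config.seed, 3])
    sets = []
    signal = [g for g in gene_index if g.startswith("SIG")]
    noise = [g for g in gene_index if g.startswith("NOISE")]
    if signal:
        sets.append(GeneSet("PLANTED_SIGNAL", "genes tracking the marker", signal))
    size = max(len(signal), 5)
    for d in range(n_decoys):
        if len(noise) < size:
            break
        members = sorted(rng.choice(noise, size=size, replace=False).tolist())
        sets.append(GeneSet(f"DECOY_{d + 1:02d}", "random decoy set", members))
    return sets


def _blob_mask(rng: np.random.Generator, size: int, fraction: float) -> np.ndarray:
    """Smooth random blobs covering ~``fraction`` of the slide."""
    low = 256
    g = gaussian_filter(rng.normal(size=(low, low)), sigma=20, mode="wrap")
    thresh = np.quantile(g, 1 - fraction)
    mask_low = g > thresh
    if size % low == 0:
        f = size // low
        return np.repeat(np.repeat(mask_low, f, axis=0), f, axis=1)
    mask = zoom(mask_low.astype(np.float32), size / low, order=1) > 0.5
    return mask[:size, :size]


def render_slide(patient: SyntheticPatient, config: CohortConfig) -> SlideImage:
    """Render the H&E-like slide of one patient.

    White background (near-saturated RGB) with tissue blobs whose texture
    smoothness depends on ``true_class`` scaled by ``texture_effect``.  The
    ground-truth blob mask is attached as ``tissue_truth``.
    """
    config.validate()
    idx = int("".join(ch for ch in patient.patient_id if ch.isdigit()))
    rng = np.random.default_rng([config.seed, 7, idx])
    s = config.slide_px
    src = SOURCE_TILE_PX[config.magnification]
    if s < src:
        raise ValueError(f"slide_px={s} smaller than one {src}-px tile")
    mask = _blob_mask(rng, s, config.tissue_fraction)
    sign = 1.0 if patient.true_class == 1 else -1.0
    sigma = BASE_SIGMA * float(np.exp(sign * config.texture_effect / 2.0))
    f = gaussian_filter(rng.standard_normal((s, s), dtype=np.float32), sigma=sigma)
    f = (f - f.mean()) / f.std()
    # nucleus/stroma mixing coefficient; clipped so the brightest tissue
    # stays clearly darker than the white background
    t = np.clip(np.float32(0.5) + np.float32(0.26) * f,
                np.float32(0.15), np.float32(1.0))
    pixels = np.empty((s, s, 3), dtype=np.uint8)
    for c in range(3):
        ch = np.float32(PINK[c]) + t * np.float32(PURPLE[c] - PINK[c])
        ch[~mask] = BACKGROUND_LEVEL
        pixels[..., c] = (ch + np.float32(0.5)).astype(np.uint8)
    slide = SlideImage(pixels, config.magnification, patient.patient_id)
    slide.tissue_truth = mask
    return slide


def write_cohort(cohort: Cohort, outdir, image_format: str = "png") -> dict:
    """Write slides (PNG/TIFF), clinical CSV, expression TSV, and GMT."""
    from pathlib import Path

    from PIL import Image

    from pathoscore.enrichment import write_gmt

    out = Path(outdir)
    slides_dir = out / "slides"
    slides_dir.mkdir(parents=True, exist_ok=True)
    for slide in cohort.slides():
        path = slides_dir / f"{slide.patient_id}.{image_format}"
        if image_format == "tiff":
            import tifffile

            tifffile.imwrite(path, slide.pixels)
        else:
            Image.fromarray(slide.pixels).save(path)
    clinical = out / "clinical.csv"
    cohort.clinical_table().to_csv(clinical, index=False)
    expr = out / "expression.tsv"
    cohort.expression.to_csv(expr, sep="\t")
    gmt = out / "gene_sets.gmt"
    write_gmt(cohort.gene_sets, gmt)
    manifest = {"slides_dir": str(slides_dir), "clinical": str(clinical),
                "expression": str(expr), "gmt": str(gmt),
                "config": asdict(cohort.config)}
    return manifest
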