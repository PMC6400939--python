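"""Seeded synthetic biopsy-image cohorts.

No public image archive exists for Hsp90-probe microendoscopy of breast
biopsies, so the pipeline ships a generator that emulates the structure such
a cohort exhibits:

* mean fluorescence ordered tumor > benign > mammoplasty (reduction-surgery
  normal tissue takes up the least probe);
* among tumors, receptor-subtype ordering Her2+ > TNBC > ER+;
* mean fluorescence decreasing with the density of tumor-infiltrating
  lymphocytes (TIL% of stroma divided by stromal %), while tumor cellularity
  is left uncoupled from intensity;
* much smoother (more homogeneous) mammoplasty images than tumor images;
* an optional non-binding control agent whose signal sits at a configurable
  fraction of the specific agent's, for specificity-ratio experiments.

Each frame is a smooth multiplicative heterogeneity field (low-pass-filtered
white noise) around the site's expected mean, plus independent Gaussian pixel
noise, clipped at zero, under a circular field-of-view mask.  All randomness
flows from one seed through a hierarchical stream (cohort -> biopsy ->
frame), so cohorts are bit-reproducible and extending a cohort does not
perturb earlier biopsies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .imaging import FluorescenceFrame

TISSUE_CLASSES = ("tumor", "benign", "mammoplasty")
SUBTYPES = ("ER+", "Her2+", "TNBC")


@dataclass(frozen=True)
class ClassParams:
    """Intensity model for one tissue class.

    baseline_mean / baseline_sd: mean site intensity (a.u.) and its
    between-biopsy spread.  heterogeneity_scale: correlation length of the
    smooth intra-frame field, in pixels.  heterogeneity_amp: field amplitude
    as a fraction of the site mean.
    """

    baseline_mean: float
    baseline_sd: float
    heterogeneity_scale: float
    heterogeneity_amp: float

    def __post_init__(self) -> None:
        if self.baseline_mean < 0 or self.baseline_sd < 0:
            raise ValueError("intensity parameters must be non-negative")
        if self.heterogeneity_scale <= 0 or self.heterogeneity_amp < 0:
            raise ValueError("heterogeneity parameters invalid")


@dataclass(frozen=True)
class AnnotationParams:
    """Distribution the per-site pathology annotations are drawn from.

    A biopsy-level value is drawn uniformly from each range; sites jitter
    around it with the given SDs (clipped back into the range).  Pathology
    endpoints such as lymphocyte infiltration are biopsy-level biology with
    modest site-to-site variation, so the biopsy, not the site, carries most
    of the variance.
    """

    pta_range: tuple[float, float] = (0.0, 0.0)
    cellularity_range: tuple[float, float] = (0.0, 0.0)
    til_range: tuple[float, float] = (0.0, 0.0)
    pta_site_sd: float = 10.0
    cellularity_site_sd: float = 5.0
    til_site_sd: float = 3.0


def _default_class_params() -> dict[str, ClassParams]:
    return {
        "tumor": ClassParams(160.0, 6.0, 20.0, 0.35),
        "benign": ClassParams(90.0, 10.0, 20.0, 0.30),
        "mammoplasty": ClassParams(55.0, 8.0, 20.0, 0.08),
    }


def _default_subtype_offsets() -> dict[str, float]:
    return {"ER+": -25.0, "Her2+": 80.0, "TNBC": 25.0}


def _default_annotation_params() -> dict[str, AnnotationParams]:
    # Tumor sites carry real pathology structure; benign and mammoplasty
    # sites have no tumor area and only sparse lymphocytes.
    return {
        "tumor": AnnotationParams((20.0, 90.0), (20.0, 60.0), (0.0, 35.0)),
        "benign": AnnotationParams((0.0, 0.0), (0.0, 0.0), (0.0, 10.0)),
        "mammoplasty": AnnotationParams((0.0, 0.0), (0.0, 0.0), (0.0, 5.0)),
    }


def _default_subtype_proportions() -> dict[str, float]:
    # Clinical cohort composition: of 27 invasive cancers, 22 were ER+ (4 of
    # those also Her2+), 5 Her2-overexpressing in total, 4 triple negative.
    # Collapsed to the three modelled categories: 18 ER+, 5 Her2+, 4 TNBC.
    return {"ER+": 18 / 27, "Her2+": 5 / 27, "TNBC": 4 / 27}


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic cohort generator.

    The defaults realise the qualitative orderings described in the module
    docstring; absolute intensity units are arbitrary because the instrument's
    dynamic range is not standardised.
    """

    frame_height: int = 256
    frame_width: int = 256
    frames_per_biopsy: int = 5
    class_params: dict[str, ClassParams] = field(default_factory=_default_class_params)
    subtype_offsets: dict[str, float] = field(default_factory=_default_subtype_offsets)
    til_slope: float = -130.0
    nonspecific_mean: float = 40.0
    noise_sd: float = 8.0
    annotation_params: dict[str, AnnotationParams] = field(
        default_factory=_default_annotation_params
    )
    subtype_proportions: dict[str, float] = field(
        default_factory=_default_subtype_proportions
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_height < 1 or self.frame_width < 1:
            raise ValueError("frame dimensions must be positive")
        if self.frames_per_biopsy < 1:
            raise ValueError("frames_per_biopsy must be >= 1")
        if self.noise_sd < 0 or self.nonspecific_mean < 0:
            raise ValueError("intensity parameters must be non-negative")
        for name in TISSUE_CLASSES:
            if name not in self.class_params:
                raise ValueError(f"class_params missing {name!r}")
        for name in SUBTYPES:
            if name not in self.subtype_offsets:
                raise ValueError(f"subtype_offsets missing {name!r}")


@dataclass(frozen=True)
class SiteAnnotation:
    """Pathology read-out for one 1-mm biopsy site.

    ``stromal_percent`` is the complement of tumor cellularity within the
    tumor area; TIL density is ``til_percent_of_stroma / stromal_percent``.
    """

    percent_tumor_area: float
    tumor_cellularity: float
    stromal_percent: float
    til_percent_of_stroma: float

    def __post_init__(self) -> None:
        for name in (
            "percent_tumor_area",
            "tumor_cellularity",
            "stromal_percent",
            "til_percent_of_stroma",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name}={v} outside [0, 100]")
        if abs(self.stromal_percent - (100.0 - self.tumor_cellularity)) > 1e-9:
            raise ValueError("stromal_percent must equal 100 - tumor_cellularity")


@dataclass
class Biopsy:
    """Ordered frames plus per-site annotations for one biopsy."""

    biopsy_id: str
    tissue_class: str
    subtype: str  # "none" for non-tumor biopsies
    frames: list[FluorescenceFrame]
    annotations: list[SiteAnnotation]
    agent: str = "specific"  # specific (binding) vs nonspecific control

    def __post_init__(self) -> None:
        if self.tissue_class not in TISSUE_CLASSES:
            raise ValueError(f"unknown tissue_class {self.tissue_class!r}")
        if len(self.frames) != len(self.annotations) or not self.frames:
            raise ValueError("frames and annotations must align and be nonempty")
        if (self.subtype == "none") != (self.tissue_class != "tumor"):
            raise ValueError("subtype must be 'none' iff tissue_class is not tumor")
        if self.agent not in ("specific", "nonspecific"):
            raise ValueError(f"unknown agent {self.agent!r}")

    @property
    def pooled_pixels(self) -> np.ndarray:
        return np.concatenate([f.masked_pixels for f in self.frames])


def circular_mask(height: int, width: int) -> np.ndarray:
    """Boolean disk inscribed in the frame, mimicking a fiber-bundle FOV."""
    yy, xx = np.mgrid[0:height, 0:width]
    cy, cx = (height - 1) / 2.0, (width - 1) / 2.0
    r = min(height, width) / 2.0
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


def til_density(annotation: SiteAnnotation) -> float:
    """TIL% of stroma divided by stromal %, the per-site lymphocyte density."""
    if annotation.stromal_percent == 0:
        raise ValueError("TIL density undefined when stromal_percent is 0")
    return annotation.til_percent_of_stroma / annotation.stromal_percent


def site_mean_intensity(
    config: GeneratorConfig,
    tissue_class: str,
    subtype: str,
    annotation: SiteAnnotation,
    baseline_shift: float = 0.0,
) -> float:
    """Expected mean intensity of a site before heterogeneity and noise."""
    cp = config.class_params[tissue_class]
    mean = cp.baseline_mean + baseline_shift
    if tissue_class == "tumor":
        mean += config.subtype_offsets[subtype]
    if annotation.til_percent_of_stroma > 0 and annotation.stromal_percent == 0:
        raise ValueError("TIL density undefined: stromal_percent is 0 with TILs present")
    if annotation.stromal_percent > 0:
        mean += config.til_slope * til_density(annotation)
    return max(mean, 0.0)


def generate_site_frame(
    config: GeneratorConfig,
    tissue_class: str,
    subtype: str,
    annotation: SiteAnnotation,
    rng: np.random.Generator,
    baseline_shift: float = 0.0,
    mean_override: float | None = None,
) -> FluorescenceFrame:
    """Render one synthetic site frame.

    The frame is ``mean * (1 + amp * G)`` with G a unit-variance smooth
    field, plus N(0, noise_sd) pixel noise, clipped at zero, under a circular
    mask.  ``mean_override`` bypasses the class/subtype/TIL model (used for
    control-agent frames).
    """
    cp = config.class_params[tissue_class]
    if mean_override is not None:
        mean = max(float(mean_override), 0.0)
    else:
        mean = site_mean_intensity(config, tissue_class, subtype, annotation, baseline_shift)

    shape = (config.frame_height, config.frame_width)
    if cp.heterogeneity_amp > 0:
        raw = rng.standard_normal(shape)
        smooth = ndimage.gaussian_filter(raw, sigma=cp.heterogeneity_scale, mode="reflect")
        sd = smooth.std()
        if sd > 0:
            smooth /= sd
        pixels = mean * (1.0 + cp.heterogeneity_amp * smooth)
    else:
        pixels = np.full(shape, mean)
    if config.noise_sd > 0:
        pixels = pixels + rng.normal(0.0, config.noise_sd, shape)
    pixels = np.clip(pixels, 0.0, None)

    mask = circular_mask(*shape)
    pixels = np.where(mask, pixels, 0.0)
    return FluorescenceFrame(pixels=pixels, mask=mask, gain=1.0, exposure=1.0,
                             session_id="synthetic")


def _draw_center(rng: np.random.Generator, lo: float, hi: float) -> float:
    return rng.uniform(lo, hi) if hi > lo else lo


def _jitter(rng: np.random.Generator, center: float, sd: float,
            lo: float, hi: float) -> float:
    if hi <= lo or sd <= 0:
        return center
    return float(np.clip(center + rng.normal(0.0, sd), lo, hi))


def _draw_annotation(
    config: GeneratorConfig,
    tissue_class: str,
    rng: np.random.Generator,
    centers: tuple[float, float, float],
) -> SiteAnnotation:
    """One site's annotation: jitter around the biopsy-level centers."""
    ap = config.annotation_params[tissue_class]
    pta_c, cell_c, til_c = centers
    pta = _jitter(rng, pta_c, ap.pta_site_sd, *ap.pta_range)
    cell = _jitter(rng, cell_c, ap.cellularity_site_sd, *ap.cellularity_range)
    til = _jitter(rng, til_c, ap.til_site_sd, *ap.til_range)
    return SiteAnnotation(
        percent_tumor_area=pta,
        tumor_cellularity=cell,
        stromal_percent=100.0 - cell,
        til_percent_of_stroma=til,
    )


def _generate_biopsy(
    config: GeneratorConfig,
    biopsy_id: str,
    tissue_class: str,
    subtype: str,
    seed_seq: np.random.SeedSequence,
    agent: str = "specific",
    mean_override: float | None = None,
) -> Biopsy:
    biopsy_rng = np.random.default_rng(seed_seq)
    cp = config.class_params[tissue_class]
    # Biopsies, not sites, are the unit of biological variation: one
    # baseline-uptake shift and one set of pathology centers per biopsy.
    shift = biopsy_rng.normal(0.0, cp.baseline_sd)
    ap = config.annotation_params[tissue_class]
    centers = (
        _draw_center(biopsy_rng, *ap.pta_range),
        _draw_center(biopsy_rng, *ap.cellularity_range),
        _draw_center(biopsy_rng, *ap.til_range),
    )
    frame_seeds = seed_seq.spawn(config.frames_per_biopsy)
    frames, annotations = [], []
    for k in range(config.frames_per_biopsy):
        frame_rng = np.random.default_rng(frame_seeds[k])
        ann = _draw_annotation(config, tissue_class, frame_rng, centers)
        frame = generate_site_frame(
            config, tissue_class, subtype, ann, frame_rng,
            baseline_shift=shift, mean_override=mean_override,
        )
        frames.append(frame)
        annotations.append(ann)
    return Biopsy(
        biopsy_id=biopsy_id,
        tissue_class=tissue_class,
        subtype=subtype,
        frames=frames,
        annotations=annotations,
        agent=agent,
    )


def _subtype_counts(config: GeneratorConfig, n_tumor: int) -> list[str]:
    """Deterministic subtype assignment scaled to the requested tumor count.

    Largest-remainder apportionment of the configured proportions, so the
    default 27-tumor cohort splits 18 ER+ / 5 Her2+ / 4 TNBC.
    """
    props = config.subtype_proportions
    names = [s for s in SUBTYPES if props.get(s, 0) > 0]
    raw = np.array([props[s] * n_tumor for s in names])
    counts = np.floor(raw).astype(int)
    remainder = n_tumor - counts.sum()
    order = np.argsort(-(raw - counts))
    for i in range(remainder):
        counts[order[i % len(names)]] += 1
    labels: list[str] = []
    for name, c in zip(names, counts):
        labels.extend([name] * c)
    return labels


def generate_cohort(
    config: GeneratorConfig,
    counts: dict[str, int] | None = None,
    seed: int | None = None,
) -> list[Biopsy]:
    """Generate a labelled cohort of biopsies.

    ``counts`` maps tissue class to the number of biopsies; the default
    mirrors the clinical cohort shape of 27 tumor / 10 benign / 6 mammoplasty.
    Reproducible under a fixed (config, seed) pair.
    """
    if counts is None:
        counts = {"tumor": 27, "benign": 10, "mammoplasty": 6}
    if any(c < 0 for c in counts.values()):
        raise ValueError("counts must be non-negative")
    if sum(counts.values()) == 0:
        raise ValueError("at least one biopsy must be requested")
    if seed is None:
        seed = config.seed

    n_total = sum(counts.get(tc, 0) for tc in TISSUE_CLASSES)
    root = np.random.SeedSequence(seed)
    biopsy_seeds = root.spawn(n_total)
    biopsies: list[Biopsy] = []
    i = 0
    for tc in TISSUE_CLASSES:
        n = counts.get(tc, 0)
        subtypes = _subtype_counts(config, n) if tc == "tumor" else ["none"] * n
        for j in range(n):
            biopsies.append(
                _generate_biopsy(
                    config,
                    biopsy_id=f"{tc}_{j:03d}",
                    tissue_class=tc,
                    subtype=subtypes[j],
                    seed_seq=biopsy_seeds[i],
                )
            )
            i += 1
    return biopsies


def generate_paired_agent_biopsies(
    config: GeneratorConfig,
    specificity_factor: float,
    n_pairs: int,
    seed: int | None = None,
) -> list[tuple[Biopsy, Biopsy]]:
    """Matched (specific, nonspecific-control) biopsy pairs.

    Control biopsies are drawn around ``nonspecific_mean``; specific biopsies
    around ``specificity_factor * nonspecific_mean``.  Used to exercise the
    specificity-ratio optimisation analysis (the pre-clinical arm design used
    4 probe + 4 control biopsies per condition).
    """
    if specificity_factor <= 0:
        raise ValueError("specificity_factor must be positive")
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if seed is None:
        seed = config.seed

    root = np.random.SeedSequence(seed)
    pair_seeds = root.spawn(2 * n_pairs)
    pairs = []
    for i in range(n_pairs):
        spec = _generate_biopsy(
            config,
            biopsy_id=f"hs27_{i:03d}",
            tissue_class="tumor",
            subtype="TNBC",
            seed_seq=pair_seeds[2 * i],
            agent="specific",
            mean_override=specificity_factor * config.nonspecific_mean,
        )
        ctrl = _generate_biopsy(
            config,
            biopsy_id=f"hs217_{i:03d}",
            tissue_class="tumor",
            subtype="TNBC",
            seed_seq=pair_seeds[2 * i + 1],
            agent="nonspecific",
            mean_override=config.nonspecific_mean,
        )
        pairs.append((spec, ctrl))
    return pairs
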