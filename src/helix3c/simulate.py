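"""Synthetic inputs with known ground truth for every pipeline stage.

Emulates (i) quantitative 3C-qPCR decay profiles — three independent
assays, each quantified in triplicate, with multiplicative log-normal
noise, reported as the mean of assay means with its SEM; (ii) a genome
tiled by consecutive TADs with log-normally distributed sizes (fly-like
70-kb or mouse-like 840-kb medians) carrying epigenetic classes D1-D4;
and (iii) a binned contact map sampled around the model decay of each
TAD's class, with across-border contacts attenuated.

Everything is driven by explicit integer seeds through
``numpy.random.default_rng`` and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fitting import ContactProfile, profile_from_arrays
from .models import HelixParams, LocalChromatinParams, model_curve
from .virtual3c import BinnedContactMap, IntervalAnnotation

__all__ = [
    "NoiseSpec",
    "GenomeSpec",
    "simulate_3c_profile",
    "simulate_genome",
    "simulate_contact_map",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Replicate structure and noise level of a simulated 3C assay.

    sigma_log is the standard deviation of the multiplicative log-normal
    noise (3C-qPCR error is scale-proportional); n_assays independent
    assays, each with n_tech technical replicates.  The reported frequency
    is the mean of assay means and the SEM is taken across assay means.
    """

    sigma_log: float = 0.1
    n_assays: int = 3
    n_tech: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_log < 0:
            raise ValueError("sigma_log must be >= 0")
        if self.n_assays < 1 or self.n_tech < 1:
            raise ValueError("replicate counts must be >= 1")


# Default per-class local-chromatin truths, patterned on fly chromatin:
# active (D1) most flexible/least compact, HP1 (D4) stiffest/most compact.
DEFAULT_CLASS_PARAMS = {
    "D1": LocalChromatinParams(K=0.85, L=10.81, S=4.15),
    "D2": LocalChromatinParams(K=1.49, L=10.56, S=4.92),
    "D3": LocalChromatinParams(K=1.34, L=10.66, S=4.85),
    "D4": LocalChromatinParams(K=2.40, L=10.32, S=5.30),
}


@dataclass(frozen=True)
class GenomeSpec:
    """Layout of a synthetic annotated genome.

    TAD sizes are log-normal with the given median (fly-like 70 kb by
    default; mouse-like TADs have a median of ~840 kb), rounded to whole
    bins with a 2-bin minimum.  Epigenetic classes are assigned per TAD
    from ``class_proportions`` ("proportions") or cyclically ("cycle",
    deterministic class counts).
    """

    n_chromosomes: int = 1
    chromosome_length_bp: int = 4_000_000
    tad_median_kb: float = 70.0
    tad_sigma_log: float = 0.3
    class_proportions: dict = field(default_factory=lambda: {
        "D1": 0.25, "D2": 0.45, "D3": 0.15, "D4": 0.15})
    class_params: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_PARAMS))
    assignment: str = "proportions"
    bin_size_kb: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if self.tad_median_kb <= 0:
            raise ValueError("median TAD size must be > 0")
        if self.assignment not in ("proportions", "cycle"):
            raise ValueError("assignment must be 'proportions' or 'cycle'")


def simulate_3c_profile(params: LocalChromatinParams, separations,
                        noise: NoiseSpec,
                        helix: HelixParams | None = None,
                        **profile_kwargs) -> ContactProfile:
    """Simulate a quantitative-3C profile from model truth.

    Per separation, draws ``n_assays x n_tech`` values
    ``X_model(s) * exp(eps)`` with ``eps ~ N(0, sigma_log^2)``; the
    reported frequency is the mean of the assay means and the SEM is the
    standard error across assay means (0 when sigma_log = 0).
    """
    seps = np.asarray(separations, dtype=float)
    truth = model_curve(seps, params, helix)
    rng = np.random.default_rng(noise.seed)
    if noise.sigma_log == 0.0:
        freqs = truth
        sems = np.zeros_like(truth)
    else:
        eps = rng.normal(0.0, noise.sigma_log,
                         size=(seps.size, noise.n_assays, noise.n_tech))
        draws = truth[:, None, None] * np.exp(eps)
        assay_means = draws.mean(axis=2)
        freqs = assay_means.mean(axis=1)
        if noise.n_assays > 1:
            sems = assay_means.std(axis=1, ddof=1) / np.sqrt(noise.n_assays)
        else:
            sems = np.zeros(seps.size)
    return profile_from_arrays(seps, freqs, sems, **profile_kwargs)


def _tad_sizes_bins(rng, spec: GenomeSpec, n_bins: int) -> list[int]:
    """Draw consecutive TAD sizes (bins) covering exactly n_bins."""
    mu = np.log(spec.tad_median_kb)
    sizes = []
    used = 0
    while used < n_bins:
        size_kb = float(np.exp(rng.normal(mu, spec.tad_sigma_log)))
        size = max(int(round(size_kb / spec.bin_size_kb)), 2)
        size = min(size, n_bins - used)
        if n_bins - used - size == 1:   # never leave a 1-bin remainder
            size += 1
        sizes.append(size)
        used += size
    if sizes[-1] < 2 and len(sizes) > 1:
        sizes[-2] += sizes.pop()
    return sizes


def simulate_genome(spec: GenomeSpec) -> tuple[IntervalAnnotation, IntervalAnnotation]:
    """Tile each chromosome with consecutive TADs and per-TAD epigenetic
    classes; returns (TAD track, epigenetic track)."""
    rng = np.random.default_rng(spec.seed)
    classes = sorted(spec.class_proportions)
    probs = np.array([spec.class_proportions[c] for c in classes])
    bs_bp = int(round(spec.bin_size_kb * 1000))
    n_bins = spec.chromosome_length_bp // bs_bp
    tad_ivs, epi_ivs = [], []
    tad_counter = 0
    for ci in range(spec.n_chromosomes):
        chrom = f"chrS{ci + 1}"
        pos = 0
        for k, size in enumerate(_tad_sizes_bins(rng, spec, n_bins)):
            start = pos * bs_bp
            end = (pos + size) * bs_bp
            tad_counter += 1
            if spec.assignment == "cycle":
                active = [c for c in classes if spec.class_proportions[c] > 0]
                label = active[(tad_counter - 1) % len(active)]
            else:
                label = classes[int(rng.choice(len(classes), p=probs))]
            tad_ivs.append((chrom, start, end, f"tad_{tad_counter:05d}"))
            epi_ivs.append((chrom, start, end, label))
            pos += size
    # merge adjacent epigenetic intervals of the same class
    merged: list[tuple] = []
    for iv in epi_ivs:
        if merged and merged[-1][0] == iv[0] and merged[-1][3] == iv[3] \
                and merged[-1][2] == iv[1]:
            prev = merged.pop()
            merged.append((iv[0], prev[1], iv[2], iv[3]))
        else:
            merged.append(iv)
    return IntervalAnnotation(tuple(tad_ivs)), IntervalAnnotation(tuple(merged))


def simulate_contact_map(tads: IntervalAnnotation, epi: IntervalAnnotation,
                         class_params: dict | None = None,
                         chromosome: str | None = None,
                         bin_size_kb: float = 5.0,
                         max_offset_bins: int = 80,
                         noise: str = "lognormal",
                         sigma_log: float = 0.1,
                         depth: float = 1e6,
                         attenuation: float = 0.1,
                         seed: int = 0) -> BinnedContactMap:
    """Sample a binned contact map from per-class model decays.

    The expected value of an in-TAD bin pair at separation s is the
    unconstrained-model frequency with that TAD's class parameters;
    cross-class pairs use the geometric mean of the two ends' model
    values.  Pairs crossing a TAD border are multiplied by
    ``attenuation`` (0 = fully insulated borders).  Noise is
    multiplicative log-normal ("lognormal"), Poisson counts at the given
    sequencing ``depth`` ("poisson"), or absent ("none").
    """
    if not 0.0 <= attenuation <= 1.0:
        raise ValueError("attenuation must lie in [0, 1]")
    if noise not in ("lognormal", "poisson", "none"):
        raise ValueError(f"unknown noise mode {noise!r}")
    class_params = dict(DEFAULT_CLASS_PARAMS if class_params is None
                        else class_params)
    if chromosome is None:
        chromosome = tads.chromosomes[0]
    bs_bp = int(round(bin_size_kb * 1000))
    n_bins = tads.chromosome_end(chromosome) // bs_bp
    if n_bins < 2:
        raise ValueError("chromosome too short for a contact map")

    class_of_bin = np.full(n_bins, "", dtype=object)
    tad_of_bin = np.full(n_bins, -1, dtype=int)
    for idx, (c, s, e, lab) in enumerate(tads.intervals):
        if c == chromosome:
            tad_of_bin[s // bs_bp:e // bs_bp] = idx
    for c, s, e, lab in epi.intervals:
        if c == chromosome:
            class_of_bin[s // bs_bp:e // bs_bp] = lab
    if np.any(tad_of_bin < 0):
        raise ValueError("TAD track does not tile the chromosome")

    # per-class unit decay values for every offset
    offsets = np.arange(1, min(max_offset_bins, n_bins - 1) + 1)
    seps = offsets * bin_size_kb
    decay = {lab: model_curve(seps, p) for lab, p in class_params.items()}

    rng = np.random.default_rng(seed)
    rows, cols, vals = [], [], []
    for oi, off in enumerate(offsets):
        i = np.arange(0, n_bins - off)
        j = i + off
        xi = np.array([decay[class_of_bin[b]][oi] for b in i])
        xj = np.array([decay[class_of_bin[b]][oi] for b in j])
        expected = np.sqrt(xi * xj)
        crossing = tad_of_bin[i] != tad_of_bin[j]
        expected = np.where(crossing, expected * attenuation, expected)
        if noise == "lognormal":
            observed = expected * np.exp(
                rng.normal(0.0, sigma_log, size=expected.size))
            observed = np.where(expected > 0, observed, 0.0)
        elif noise == "poisson":
            observed = rng.poisson(depth * expected).astype(float) / depth
        else:
            observed = expected
        rows.append(i)
        cols.append(j)
        vals.append(observed)
    return BinnedContactMap.from_coo(
        chromosome, n_bins,
        np.concatenate(rows), np.concatenate(cols), np.concatenate(vals),
        bin_size_kb=bin_size_kb)
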