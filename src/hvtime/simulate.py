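"""Ground-truth simulator for expression time courses, gene sets and plates.

The generator emulates the statistical structure the analysis assumes:

* per array, a right-skewed unimodal raw-intensity histogram whose mode
  sits at zero — a Gaussian background (the majority of probes) plus a
  log-normal right tail of expressed genes;
* a minority of hypervariable genes whose group means rise monotonically
  over the 0–3 h time course (linear ramp or saturating exponential), with
  amplitude expressed in units of the replicate noise SD;
* occasional single-replicate artifacts: a stable gene with one sample
  spiked by ten noise SDs;
* per-array affine distortions applied on the log10 scale, and replicate
  noise on the same scale.

Raw values are produced by inverting the normalization model: expressed
log-signal -> per-array affine distortion -> z = 10^log -> raw =
background_mean + background_sd * z. The generating background model and
distortions are recorded in the truth object, so every pipeline stage can
be checked against known parameters. One global seed is split into
independent streams (gene roles, array distortions, noise), so enlarging
the gene panel does not perturb the array distortions.

The default design mirrors a two-arm time-course study sharing an
untreated 0 h baseline: two treatments sampled at 0.5, 1, 2 and 3 h, two
replicate arrays per group, on a 24,526-probe panel.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .containers import (
    BackgroundModel,
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    SampleInfo,
    ViabilitySeries,
)
from .errors import ConfigError

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "generate_timecourse",
    "generate_gmt",
    "generate_plate",
]

BASELINE_TREATMENT = "untreated"


@dataclass
class SimulationConfig:
    """Generating parameters of a synthetic time course.

    Fractions: ``background_fraction`` of all genes are pure background;
    among the expressed remainder, ``hv_fraction`` are hypervariable and
    ``artifact_fraction`` carry a single-replicate spike. ``hv_effect_size``
    is the trend amplitude in units of the replicate noise SD (log10
    scale). Distortion ranges are per-array affine parameters on the log10
    scale; ``identity_distortions`` forces slope 1 / offset 0.
    """

    seed: int
    n_genes: int = 24526
    treatments: tuple[str, ...] = ("frankincense", "sandalwood")
    times: tuple[float, ...] = (0.5, 1.0, 2.0, 3.0)
    n_replicates: int = 2
    background_fraction: float = 0.6
    hv_fraction: float = 0.05
    artifact_fraction: float = 0.01
    background_sd: float = 50.0
    baseline_log_mean: float = 1.2
    baseline_log_sd: float = 0.35
    baseline_log_min: float = 0.6
    hv_effect_size: float = 5.0
    noise_sd: float = 0.05
    artifact_spike: float = 10.0
    slope_range: tuple[float, float] = (0.92, 1.08)
    offset_range: tuple[float, float] = (-0.08, 0.08)
    identity_distortions: bool = False
    trend_shapes: tuple[str, ...] = ("linear", "saturating")

    def __post_init__(self) -> None:
        for name in ("background_fraction", "hv_fraction", "artifact_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.hv_fraction + self.artifact_fraction > 1.0:
            raise ConfigError("hv_fraction + artifact_fraction exceed 1")
        if self.hv_effect_size <= 0 or self.noise_sd <= 0 or self.background_sd <= 0:
            raise ConfigError("effect size, noise_sd and background_sd must be > 0")
        if self.n_genes < 1 or self.n_replicates < 1 or not self.treatments:
            raise ConfigError("need genes, replicates and at least one treatment")
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        unknown = set(self.trend_shapes) - {"linear", "saturating"}
        if unknown:
            raise ConfigError(f"unknown trend shapes {sorted(unknown)}")

    def groups(self) -> list[tuple[str, float]]:
        out = [(BASELINE_TREATMENT, 0.0)]
        for trt in self.treatments:
            out.extend((trt, t) for t in self.times)
        return out


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated dataset.

    ``labels`` maps probe -> {background, expressed_stable, hv, artifact};
    ``hv_treatments`` names the arm(s) a truth-HV gene responds to;
    ``spiked_sample`` names the corrupted array of each artifact gene;
    ``background_model`` is the exact generating normalization model.
    """

    labels: pd.Series
    hv_treatments: Mapping[str, tuple[str, ...]]
    trend_shape: Mapping[str, str]
    spiked_sample: Mapping[str, str]
    background_model: BackgroundModel
    config: SimulationConfig

    def probes(self, label: str) -> list[str]:
        return list(self.labels.index[self.labels == label])


def _trend(shape: str, t: np.ndarray) -> np.ndarray:
    """Monotone 0 -> 1 trend over the time course (t in hours, max 3 h)."""
    tmax = t.max() if t.size and t.max() > 0 else 1.0
    if shape == "linear":
        return t / tmax
    return (1.0 - np.exp(-1.5 * t)) / (1.0 - np.exp(-1.5 * tmax))


def generate_timecourse(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Simulate a raw genes × arrays matrix with full ground truth.

    Identical config (including seed) gives bitwise-identical output.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_genes, rng_arrays, rng_noise = (
        np.random.default_rng(c) for c in ss.spawn(3)
    )

    groups = config.groups()
    samples: list[SampleInfo] = []
    for trt, t in groups:
        for r in range(1, config.n_replicates + 1):
            tlab = f"{t:g}".replace(".", "p")
            samples.append(
                SampleInfo(f"{trt}_{tlab}h_r{r}", treatment=trt, time_hours=t, replicate=r)
            )
    array_ids = [s.array_id for s in samples]
    n_arrays = len(samples)
    times = np.array([s.time_hours for s in samples])

    n = config.n_genes
    n_background = int(round(n * config.background_fraction))
    n_expressed = n - n_background
    n_hv = int(round(n_expressed * config.hv_fraction))
    n_artifact = int(round(n_expressed * config.artifact_fraction))
    if n_hv + n_artifact > n_expressed:
        raise ConfigError("hv + artifact genes exceed expressed genes")

    probes = [f"PRB_{i:06d}" for i in range(n)]
    perm = rng_genes.permutation(n)
    bg_idx = perm[:n_background]
    expr_idx = perm[n_background:]
    hv_idx = expr_idx[:n_hv]
    art_idx = expr_idx[n_hv : n_hv + n_artifact]

    labels = np.array(["expressed_stable"] * n, dtype=object)
    labels[bg_idx] = "background"
    labels[hv_idx] = "hv"
    labels[art_idx] = "artifact"

    # per-array distortions (own stream: stable under panel-size changes)
    if config.identity_distortions:
        slopes = np.ones(n_arrays)
        offsets = np.zeros(n_arrays)
    else:
        slopes = rng_arrays.uniform(*config.slope_range, size=n_arrays)
        offsets = rng_arrays.uniform(*config.offset_range, size=n_arrays)

    # expressed-gene baselines: truncated log-normal in log10(z) space
    base = np.empty(n_expressed)
    remaining = np.arange(n_expressed)
    while remaining.size:
        draw = rng_genes.normal(
            config.baseline_log_mean, config.baseline_log_sd, size=remaining.size
        )
        ok = draw >= config.baseline_log_min
        base[remaining[ok]] = draw[ok]
        remaining = remaining[~ok]

    shapes = rng_genes.choice(config.trend_shapes, size=n_hv)
    arm_choices = [(t,) for t in config.treatments]
    if len(config.treatments) > 1:
        arm_choices.append(tuple(config.treatments))
    arms = [arm_choices[i] for i in rng_genes.integers(0, len(arm_choices), size=n_hv)]
    spike_cols = rng_genes.integers(0, n_arrays, size=n_artifact)

    amplitude = config.hv_effect_size * config.noise_sd
    log_means = np.tile(base[:, None], (1, n_arrays))  # expressed genes only
    pos_of = {int(g): row for row, g in enumerate(expr_idx)}
    trt_per_array = np.array([s.treatment for s in samples], dtype=object)
    for j, g in enumerate(hv_idx):
        row = pos_of[int(g)]
        responding = np.isin(trt_per_array, arms[j])
        profile = _trend(shapes[j], times) * amplitude
        log_means[row, responding] += profile[responding]

    logv = log_means + rng_noise.normal(0.0, config.noise_sd, size=log_means.shape)
    for j, g in enumerate(art_idx):
        row = pos_of[int(g)]
        logv[row, spike_cols[j]] += config.artifact_spike * config.noise_sd

    distorted = logv * slopes[None, :] + offsets[None, :]
    z = 10.0**distorted

    raw = np.empty((n, n_arrays))
    raw[bg_idx] = rng_noise.normal(0.0, config.background_sd, size=(n_background, n_arrays))
    raw[expr_idx] = config.background_sd * z

    truth_model = BackgroundModel(
        per_array={aid: (0.0, config.background_sd) for aid in array_ids},
        alignment={
            aid: (float(s), float(o)) for aid, s, o in zip(array_ids, slopes, offsets)
        },
        reference_id="generating-truth",
    )
    matrix = ExpressionMatrix(
        pd.DataFrame(raw, index=probes, columns=array_ids), samples, value_space="raw"
    )
    truth = SyntheticTruth(
        labels=pd.Series(labels, index=probes, name="label"),
        hv_treatments={probes[int(g)]: arms[j] for j, g in enumerate(hv_idx)},
        trend_shape={probes[int(g)]: str(shapes[j]) for j, g in enumerate(hv_idx)},
        spiked_sample={
            probes[int(g)]: array_ids[int(spike_cols[j])]
            for j, g in enumerate(art_idx)
        },
        background_model=truth_model,
        config=config,
    )
    return matrix, truth


def generate_gmt(
    truth: SyntheticTruth,
    n_random_sets: int = 10,
    set_size: tuple[int, int] = (20, 60),
    enriched_size: int = 40,
    enriched_hv_fraction: float = 0.8,
    seed: Optional[int] = None,
) -> GeneSetCollection:
    """Annotation sets with one set enriched in truth-HV genes.

    The enriched set draws ``enriched_hv_fraction`` of its members from the
    truth-HV genes and the rest at random; ``n_random_sets`` further sets
    are drawn uniformly from the whole panel.
    """
    rng = np.random.default_rng(
        truth.config.seed + 777 if seed is None else seed
    )
    all_genes = np.array(truth.labels.index)
    hv = np.array(truth.probes("hv"))
    non_hv = np.array(truth.labels.index[truth.labels != "hv"])
    n_hv_members = min(int(round(enriched_size * enriched_hv_fraction)), hv.size)
    members = list(rng.choice(hv, size=n_hv_members, replace=False)) + list(
        rng.choice(non_hv, size=enriched_size - n_hv_members, replace=False)
    )
    sets = [GeneSet("HV_ENRICHED", "synthetic HV-enriched set", frozenset(members))]
    for i in range(n_random_sets):
        size = int(rng.integers(set_size[0], set_size[1] + 1))
        sets.append(
            GeneSet(
                f"RANDOM_{i:03d}",
                "synthetic random set",
                frozenset(rng.choice(all_genes, size=size, replace=False)),
            )
        )
    return GeneSetCollection(sets)


def generate_plate(
    ic50_dilution: float,
    hill_slope: float = 2.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    dilution_factors: Optional[Sequence[float]] = None,
    n_replicates: int = 3,
    baseline_absorbance: float = 0.4,
    growth_factor: float = 1.8,
) -> ViabilitySeries:
    """Simulate an XTT plate with a logistic dose-response curve.

    Relative viability follows 1 / (1 + (d50/d)^hill) in the dilution
    factor d (so high dilution -> viability 1), centred at the requested
    IC50; Gaussian noise of ``noise_sd`` is added to each absorbance.
    """
    if ic50_dilution <= 0:
        raise ConfigError("ic50_dilution must be > 0")
    rng = np.random.default_rng(seed)
    if dilution_factors is None:
        dilution_factors = list(ic50_dilution * np.logspace(-0.9, 0.9, 9))
    d = np.asarray(dilution_factors, dtype=float)
    viability = 1.0 / (1.0 + (ic50_dilution / d) ** hill_slope)

    def wells(mean: float) -> list[float]:
        return list(mean + noise_sd * rng.standard_normal(n_replicates))

    t0 = {float(x): wells(baseline_absorbance) for x in d}
    t24 = {
        float(x): wells(baseline_absorbance * growth_factor * v)
        for x, v in zip(d, viability)
    }
    return ViabilitySeries(
        dilution_factors=[float(x) for x in d],
        absorbance_t0=t0,
        absorbance_t24=t24,
        control_t0=wells(baseline_absorbance),
        control_t24=wells(baseline_absorbance * growth_factor),
    )
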