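"""Synthetic neurons, feature tables, degree sequences, and projections.

Every generator is a pure function of its spec and seed. The feature-table
generator uses a class-mean-plus-noise model: neurons of one class share a
latent mean vector, so intra-class feature vectors correlate more strongly
than inter-class ones — the ordering every class-level analysis assumes —
while a zero mean-shift scale yields exchangeable data for null
calibration. SWC trees are grown as random rooted binary-branching
neurites; projection matrices couple edge strength to region similarity via
a mixing weight rho in [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .morpho_io import FeatureTable, NeuronReconstruction, SwcNode
from .projection import RegionMatrix

__all__ = [
    "SynthSpec",
    "synth_feature_table",
    "synth_swc",
    "synth_projection",
    "synth_degree_sequence",
]


@dataclass
class SynthSpec:
    """Parameters of the synthetic generators.

    ``classes`` maps class name -> size; ``within_class_corr`` is the target
    expected Pearson correlation between same-class neurons (it fixes the
    class-mean scale as sd_class = noise_sd * sqrt(w / (1 - w))); a
    ``class_scale`` given explicitly overrides that. Defaults mirror the
    study conditions the analyses assume: 42 features per neuron, class
    structure strong enough that intra-class similarity clearly exceeds
    inter-class similarity, unit measurement noise.
    """

    n_neurons: int = 120
    n_features: int = 42
    classes: dict[str, int] = field(
        default_factory=lambda: {"A": 40, "B": 40, "C": 40}
    )
    within_class_corr: float = 0.3
    class_scale: float | None = None
    noise_sd: float = 1.0
    seed: int | None = None
    # SWC growth
    n_stems: int = 2
    branching_prob: float = 0.4
    max_depth: int = 5
    segment_length: float = 20.0
    nodes_per_branch: int = 4
    angle_jitter: float = 0.3
    # projections
    rho: float = 0.5
    zero_fraction: float = 0.3

    def __post_init__(self) -> None:
        if sum(self.classes.values()) != self.n_neurons:
            raise ValueError("class sizes must sum to n_neurons")
        if not 0 <= self.within_class_corr < 1:
            raise ValueError("within_class_corr must lie in [0, 1)")
        if not 0 <= self.rho <= 1:
            raise ValueError("rho must lie in [0, 1]")
        if self.n_features < 3 or self.n_neurons < 3:
            raise ValueError("need at least 3 neurons and 3 features")

    @property
    def scale(self) -> float:
        if self.class_scale is not None:
            return self.class_scale
        w = self.within_class_corr
        return self.noise_sd * math.sqrt(w / (1 - w)) if w > 0 else 0.0


def synth_feature_table(spec: SynthSpec) -> FeatureTable:
    """Class-structured neuron x feature table with ground-truth labels.

    Features of a neuron in class c are mu_c + noise, with mu_c drawn once
    per class with sd ``spec.scale`` and noise sd ``spec.noise_sd``. The
    class of each neuron is recorded in the metadata column ``class``.
    """
    rng = np.random.default_rng(spec.seed)
    rows, labels, classes = [], [], []
    for cname, size in spec.classes.items():
        mu = rng.normal(0.0, spec.scale, size=spec.n_features)
        for i in range(size):
            rows.append(mu + rng.normal(0.0, spec.noise_sd, size=spec.n_features))
            labels.append(f"{cname}_{i:03d}")
            classes.append(cname)
    values = pd.DataFrame(
        np.asarray(rows), index=labels,
        columns=[f"f{j:02d}" for j in range(spec.n_features)],
    )
    meta = pd.DataFrame({"class": classes}, index=labels)
    return FeatureTable(values, meta)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _jitter(direction: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    if sd == 0:
        return direction
    return _unit(direction + rng.normal(0.0, sd, size=3))


def synth_swc(spec: SynthSpec, label: str = "synth") -> NeuronReconstruction:
    """Grow one random rooted neuron satisfying all SWC tree invariants.

    A soma root sprouts ``n_stems`` neurites; each branch is a chain of
    ``nodes_per_branch`` compartments of length segment_length /
    nodes_per_branch with direction jitter ``angle_jitter``; at a branch
    end, with probability ``branching_prob`` (and below ``max_depth``) the
    neurite bifurcates into two daughters, else it terminates.
    """
    rng = np.random.default_rng(spec.seed)
    soma_radius = float(rng.uniform(3.0, 8.0))
    nodes = [SwcNode(1, 1, 0.0, 0.0, 0.0, soma_radius, -1)]
    next_id = 2
    step = spec.segment_length / max(spec.nodes_per_branch, 1)

    def grow(parent_id: int, pos: np.ndarray, direction: np.ndarray,
             radius: float, depth: int) -> None:
        nonlocal next_id
        for _ in range(spec.nodes_per_branch):
            direction = _jitter(direction, spec.angle_jitter, rng)
            pos = pos + direction * step
            nodes.append(
                SwcNode(next_id, 3, float(pos[0]), float(pos[1]), float(pos[2]),
                        radius, parent_id)
            )
            parent_id = next_id
            next_id += 1
        if depth < spec.max_depth and rng.random() < spec.branching_prob:
            for sign in (1.0, -1.0):
                tilt = _unit(direction + sign * 0.6 * _unit(rng.normal(size=3)))
                grow(parent_id, pos.copy(), tilt, radius * 0.8, depth + 1)

    for s in range(spec.n_stems):
        theta = 2 * math.pi * (s + rng.random() * 0.5) / max(spec.n_stems, 1)
        direction = np.array([math.cos(theta), math.sin(theta), 0.0])
        if spec.angle_jitter > 0:
            direction = _jitter(direction, 0.2, rng)
        start = direction * soma_radius
        first = start + direction * step
        nodes.append(
            SwcNode(next_id, 3, float(first[0]), float(first[1]), float(first[2]),
                    1.0, 1)
        )
        parent = next_id
        next_id += 1
        grow(parent, first, direction, 1.0, 0)
    return NeuronReconstruction(label, nodes)


def synth_swc_population(spec: SynthSpec, n: int) -> list[NeuronReconstruction]:
    """Independent random neurons with per-neuron derived seeds."""
    rng = np.random.default_rng(spec.seed)
    out = []
    for i in range(n):
        sub = SynthSpec(**{**spec.__dict__, "seed": int(rng.integers(2**31))})
        out.append(synth_swc(sub, label=f"neuron_{i:04d}"))
    return out


def synth_projection(
    region_sim: RegionMatrix, rho: float, seed: int | None = None,
    zero_fraction: float = 0.3,
) -> RegionMatrix:
    """Projection matrix whose strengths couple to region similarity.

    Strength = rho * rank-transformed similarity + (1 - rho) * independent
    uniform noise, with the weakest ``zero_fraction`` of entries set to 0 to
    emulate absent projections. Output is symmetric with a zero diagonal.
    """
    if not 0 <= rho <= 1:
        raise ValueError("rho must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = region_sim.n
    iu = np.triu_indices(n, k=1)
    s = region_sim.values[iu]
    ranks = np.argsort(np.argsort(s)) / max(len(s) - 1, 1)
    noise = rng.uniform(0.0, 1.0, size=len(s))
    strength = rho * ranks + (1.0 - rho) * noise
    if zero_fraction > 0:
        cut = np.quantile(strength, zero_fraction)
        strength = np.where(strength <= cut, 0.0, strength)
    out = np.zeros((n, n))
    out[iu] = strength
    out = out + out.T
    return RegionMatrix(region_sim.labels, out, symmetric=True)


def _model_pmf(model: str, params: dict, k_max: int) -> np.ndarray:
    k = np.arange(1, k_max + 1, dtype=float)
    if model == "power_law":
        logp = (params["alpha"] - 1.0) * np.log(k)
    elif model == "exponential":
        logp = -k / params["k_c"]
    elif model == "truncated_power_law":
        logp = (params["alpha"] - 1.0) * np.log(k) - k / params["k_c"]
    else:
        raise ValueError(f"unknown model {model!r}")
    logp -= logp.max()
    p = np.exp(logp)
    return p / p.sum()


def synth_degree_sequence(
    model: str, params: dict, n: int, seed: int | None = None,
    k_max: int | None = None,
) -> np.ndarray:
    """I.i.d. degrees from a discrete distribution restricted to k >= 1.

    Models: ``power_law`` P(k) ~ k^(alpha-1) (requires alpha < 1 unless a
    finite ``k_max`` is given), ``exponential`` P(k) ~ e^(-k/k_c), and
    ``truncated_power_law`` P(k) ~ k^(alpha-1) e^(-k/k_c).
    """
    if n < 0:
        raise ValueError("n must be nonnegative")
    if n == 0:
        return np.array([], dtype=int)
    if k_max is None:
        if model == "power_law":
            if params.get("alpha", 1.0) >= 1.0:
                raise ValueError("pure power law with alpha >= 1 needs explicit k_max")
            k_max = 100_000
        else:
            k_max = int(50 * params["k_c"] + 100)
    pmf = _model_pmf(model, params, k_max)
    rng = np.random.default_rng(seed)
    return rng.choice(np.arange(1, k_max + 1), size=n, p=pmf).astype(int)
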