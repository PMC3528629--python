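"""Planted-cluster benchmark generator for the whole fusion pipeline.

Real inputs for this kind of analysis (growth-inhibition profiles over
a cell-line panel, structural fingerprints, bioassay target
annotations) require large downloads; this module generates all three
with a known planted partition so every stage — view construction,
fusion, eta tuning, clustering, target-network validation, screening —
can be exercised and checked against ground truth.

The generative model is deliberately the simplest one matched to each
view's similarity metric:

* profiles: each cluster draws a standard-normal center profile;
  a compound is its cluster center plus i.i.d. Gaussian noise with
  standard deviation ``view_noise[0]``, optionally plus a per-compound
  scalar offset (a vertical dose shift changes Euclidean distance but
  leaves the Pearson correlation untouched);
* fingerprints: each cluster draws a Bernoulli(density) template; each
  compound flips every template bit independently with probability
  ``view_noise[1] / 2`` (so noise 1 gives uniformly random bits and no
  signal);
* targets: each cluster owns ``targets_per_cluster`` dedicated targets
  hit by all members; each compound additionally hits one random
  foreign target with probability ``annotation_noise``.

The default scenario mirrors the scale of a curated growth-inhibition
panel study: 37 compounds, 6 planted clusters, 60 profile features,
1024 fingerprint bits, per-view noise 0.2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import BipartiteNetwork, CompoundProfileSet, FingerprintSet

FINGERPRINT_DENSITY = 0.3

__all__ = [
    "PlantedScenario",
    "generate_profiles",
    "generate_fingerprints",
    "generate_targets",
    "generate_all",
]


@dataclass
class PlantedScenario:
    """Parameters of one planted-partition benchmark instance.

    ``labels`` (1..k_true, contiguous blocks of near-equal size) are
    derived, not supplied.
    """

    n: int = 37
    k_true: int = 6
    view_noise: tuple[float, float] = (0.2, 0.2)
    profile_dim: int = 60
    fp_bits: int = 1024
    targets_per_cluster: int = 3
    annotation_noise: float = 0.05
    profile_offset_sd: float = 0.0
    seed: int = 0
    labels: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if not 2 <= self.k_true <= self.n:
            raise ValueError("need n >= k_true >= 2")
        if not all(0.0 <= v <= 1.0 for v in self.view_noise):
            raise ValueError("view_noise levels must lie in [0, 1]")
        if not 0.0 <= self.annotation_noise <= 1.0:
            raise ValueError("annotation_noise must lie in [0, 1]")
        sizes = np.full(self.k_true, self.n // self.k_true)
        sizes[: self.n % self.k_true] += 1
        self.labels = np.repeat(np.arange(1, self.k_true + 1), sizes)

    @property
    def compound_ids(self) -> list[str]:
        return [f"C{i + 1:03d}" for i in range(self.n)]

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


def generate_profiles(sc: PlantedScenario) -> CompoundProfileSet:
    """Bioactivity profiles with cluster-center structure.

    At ``view_noise[0] = 0`` every within-cluster pair has Pearson
    correlation exactly 1 (scalar offsets preserve shape).
    """
    if sc.profile_dim < 3:
        raise ValueError("profile_dim must be >= 3")
    rng = sc._rng(1)
    centers = rng.normal(size=(sc.k_true, sc.profile_dim))
    noise = rng.normal(size=(sc.n, sc.profile_dim)) * sc.view_noise[0]
    X = centers[sc.labels - 1] + noise
    if sc.profile_offset_sd > 0:
        X = X + rng.normal(scale=sc.profile_offset_sd, size=(sc.n, 1))
    features = [f"cell{j + 1:02d}" for j in range(sc.profile_dim)]
    return CompoundProfileSet(sc.compound_ids, features, X)


def generate_fingerprints(sc: PlantedScenario) -> FingerprintSet:
    """Binary fingerprints as noisy copies of per-cluster templates.

    Every compound is guaranteed at least one set bit (an all-zero
    fingerprint has no defined Tanimoto self-similarity).
    """
    if sc.fp_bits < 8:
        raise ValueError("fp_bits must be >= 8")
    rng = sc._rng(2)
    templates = (rng.random((sc.k_true, sc.fp_bits)) < FINGERPRINT_DENSITY).astype(np.uint8)
    flip = rng.random((sc.n, sc.fp_bits)) < sc.view_noise[1] / 2.0
    bits = templates[sc.labels - 1] ^ flip.astype(np.uint8)
    empty = bits.sum(axis=1) == 0
    if empty.any():
        cols = rng.integers(0, sc.fp_bits, size=int(empty.sum()))
        bits[np.flatnonzero(empty), cols] = 1
    return FingerprintSet(sc.compound_ids, bits)


def generate_targets(sc: PlantedScenario) -> BipartiteNetwork:
    """Compound-target edges: per-cluster shared targets plus noise.

    At ``annotation_noise = 0`` the one-mode projection is a disjoint
    union of cluster cliques.
    """
    rng = sc._rng(3)
    ids = sc.compound_ids
    targets = [
        f"T{c}_{j + 1}" for c in range(1, sc.k_true + 1) for j in range(sc.targets_per_cluster)
    ]
    edges: set[tuple[str, str]] = set()
    for i, lab in enumerate(sc.labels):
        for j in range(sc.targets_per_cluster):
            edges.add((ids[i], f"T{lab}_{j + 1}"))
    for i, lab in enumerate(sc.labels):
        if rng.random() < sc.annotation_noise:
            foreign = [t for t in targets if not t.startswith(f"T{lab}_")]
            if foreign:
                edges.add((ids[i], foreign[rng.integers(0, len(foreign))]))
    return BipartiteNetwork(ids, targets, edges)


def generate_all(sc: PlantedScenario):
    """All three inputs plus the planted labels for one scenario."""
    return generate_profiles(sc), generate_fingerprints(sc), generate_targets(sc), sc.labels.copy()
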