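"""Synthetic cell tables with planted ground truth.

Everything the tests and examples consume is generated here, as pure
functions of their arguments (seed included):

* the nine-neuron toy classification — eight pyramidal neurons first split
  into two size groups, then reclassified into three groups once a ninth,
  intermediate-sized neuron arrives; the original eight carry both
  annotations while the ninth is missing the first-pass label;
* paired taxonomies with a known row-stochastic mixing matrix, for
  exercising harmonization parameter recovery;
* clustered numeric tables (two Gaussian coordinate columns plus a separated
  feature) standing in for embeddings, spatial positions or
  electrophysiological measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CATEGORICAL, NUMERIC, CellTable, ValidationError

__all__ = [
    "MixingSpec",
    "make_toy_neurons",
    "make_taxonomy_pair",
    "make_numeric_fixture",
]

# --- toy-neuron constants ---------------------------------------------------
# Sizes chosen so the two-group split (small <= 15 < large) and the
# three-group split (small <= 13 < medium <= 19 < large) nest consistently:
# first-pass "small" cells stay small, first-pass "large" cells divide into
# medium and large, and the ninth neuron lands in the new medium group.
_TOY_SIZES = [10.0, 11.0, 12.0, 13.0, 18.0, 19.0, 22.0, 23.0, 16.0]
_V1_THRESHOLD = 15.0
_V2_THRESHOLDS = (13.0, 19.0)

# --- numeric-fixture constants ---------------------------------------------
#: Distance between adjacent cluster centers along the first coordinate.
CLUSTER_SPACING = 6.0
#: Within-cluster standard deviation of both coordinates.
COORD_SD = 1.0
#: Per-cluster offset and SD of the extra separated feature.
FEATURE_SPACING = 4.0
FEATURE_SD = 1.0


def make_toy_neurons() -> CellTable:
    """The 8/9-neuron worked example of a shifting size classification.

    Returns nine records: ``size`` (numeric), ``size_v1`` (two categories,
    missing for the ninth neuron, which did not exist at first
    classification) and ``size_v2`` (three categories, defined for all
    nine). Exactly eight records are complete in both categorical columns.
    """
    sizes = np.array(_TOY_SIZES)
    v1 = np.array(
        ["small" if s <= _V1_THRESHOLD else "large" for s in sizes], dtype=object
    )
    v1[8] = np.nan  # the ninth neuron arrived after the first classification
    lo, hi = _V2_THRESHOLDS
    v2 = np.array(
        [
            "small" if s <= lo else ("medium" if s <= hi else "large")
            for s in sizes
        ],
        dtype=object,
    )
    data = pd.DataFrame({"size": sizes, "size_v1": v1, "size_v2": v2})
    ids = [f"neuron_{i + 1}" for i in range(9)]
    return CellTable(
        ids,
        data,
        {"size": NUMERIC, "size_v1": CATEGORICAL, "size_v2": CATEGORICAL},
    )


@dataclass
class MixingSpec:
    """Planted ground truth for a two-taxonomy pairing.

    ``matrix[i, j]`` is the probability that a cell with reference label
    ``ref_labels[i]`` carries study label ``study_labels[j]``; each row must
    sum to 1. ``counts[i]`` cells are generated per reference label.
    """

    ref_labels: list[str]
    study_labels: list[str]
    counts: list[int]
    matrix: np.ndarray
    seed: int = 0

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.shape != (len(self.ref_labels), len(self.study_labels)):
            raise ValidationError("mixing matrix shape mismatch")
        if len(self.counts) != len(self.ref_labels):
            raise ValidationError("one count per reference label required")
        if any(c <= 0 for c in self.counts):
            raise ValidationError("cell counts must be positive")
        sums = self.matrix.sum(axis=1)
        if np.abs(sums - 1.0).max() > 1e-9:
            raise ValidationError(f"mixing matrix rows must sum to 1; got {sums}")


def make_taxonomy_pair(spec: MixingSpec) -> CellTable:
    """One record per planted cell, with columns ``ref_label`` and
    ``study_label`` drawn from the mixing matrix at the spec's seed."""
    rng = np.random.default_rng(spec.seed)
    ref_out: list[str] = []
    study_out = []
    for i, (label, n) in enumerate(zip(spec.ref_labels, spec.counts)):
        ref_out.extend([label] * n)
        draws = rng.choice(len(spec.study_labels), size=n, p=spec.matrix[i])
        study_out.append(draws)
    study_idx = np.concatenate(study_out)
    study = np.array(spec.study_labels, dtype=object)[study_idx]
    n_total = len(ref_out)
    data = pd.DataFrame(
        {
            "ref_label": np.array(ref_out, dtype=object),
            "study_label": study,
        }
    )
    ids = [f"cell_{i:07d}" for i in range(n_total)]
    return CellTable(
        ids, data, {"ref_label": CATEGORICAL, "study_label": CATEGORICAL}
    )


def make_numeric_fixture(n: int, k_clusters: int, seed: int = 0) -> CellTable:
    """Clustered numeric annotations: ``cluster`` plus coordinates ``x``,
    ``y`` from cluster-specific Gaussians and a separated ``feature``.

    Cluster ``i`` is centered at ``(i * CLUSTER_SPACING, -i * CLUSTER_SPACING)``
    with SD :data:`COORD_SD` in both coordinates; ``feature`` is Gaussian
    around ``i * FEATURE_SPACING`` with SD :data:`FEATURE_SD`. Records are
    assigned round-robin so cluster sizes differ by at most one.
    """
    if not (n >= k_clusters >= 1):
        raise ValidationError(f"need n >= k_clusters >= 1, got n={n}, k={k_clusters}")
    rng = np.random.default_rng(seed)
    assignment = np.arange(n) % k_clusters
    x = assignment * CLUSTER_SPACING + rng.normal(0.0, COORD_SD, size=n)
    y = -assignment * CLUSTER_SPACING + rng.normal(0.0, COORD_SD, size=n)
    feature = assignment * FEATURE_SPACING + rng.normal(0.0, FEATURE_SD, size=n)
    clusters = np.array([f"cluster_{i}" for i in assignment], dtype=object)
    data = pd.DataFrame(
        {"cluster": clusters, "x": x, "y": y, "feature": feature}
    )
    ids = [f"cell_{i:06d}" for i in range(n)]
    return CellTable(
        ids,
        data,
        {
            "cluster": CATEGORICAL,
            "x": NUMERIC,
            "y": NUMERIC,
            "feature": NUMERIC,
        },
    )
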