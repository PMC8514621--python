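"""Antigen-type classification of antibodies from CDR surface descriptors.

A leave-one-out nearest-neighbour count classifier: for each antibody the
5% most similar CDRs (by shape or electrostatic descriptor distance) form
its neighbour set, and N_pb -- the number of protein-binding antibodies in
that set -- is the classification score.  Shape and electrostatic counts
are combined as the weighted average

    N_pb_bar = A * N_pb_elec + (1 - A) * N_pb_shape,   A in [0, 1]

and an antibody is called protein-binding when its (combined) count
strictly exceeds the uniform expectation Ex[N_pb] = k * N_prot / N_tot,
i.e. the count a label-blind neighbour draw of size k would give.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .compare import mann_whitney_auc, roc_points, similarity_elec, similarity_shape
from .zernike import DescriptorTriple

__all__ = [
    "AntibodyEntry", "ClassifierConfig", "neighbor_counts", "combine_weighted",
    "predict_labels", "roc_analysis", "sweep",
]

LABELS = ("protein", "nonprotein")


@dataclass
class AntibodyEntry:
    """One antibody: id, antigen-type label, and descriptor triples keyed by
    CDR shell fraction (1.0 = the full combined-CDR patch)."""

    id: str
    label: str
    descriptors: dict[float, DescriptorTriple]

    def __post_init__(self):
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}")
        if not self.descriptors:
            raise ValueError("entry needs at least one descriptor triple")

    @classmethod
    def from_triple(cls, id: str, label: str, triple: DescriptorTriple,
                    ) -> "AntibodyEntry":
        return cls(id=id, label=label, descriptors={1.0: triple})

    def triple(self, shell_fraction: float = 1.0) -> DescriptorTriple:
        try:
            return self.descriptors[shell_fraction]
        except KeyError:
            raise KeyError(f"entry {self.id!r} has no descriptors at shell "
                           f"fraction {shell_fraction}") from None


@dataclass(frozen=True)
class ClassifierConfig:
    neighbor_fraction: float = 0.05
    weight_A: float = 0.4
    order_max: int = 20
    shell_fraction: float = 1.0

    def __post_init__(self):
        if not 0.0 < self.neighbor_fraction < 1.0:
            raise ValueError("neighbor_fraction must be in (0, 1)")
        if not 0.0 <= self.weight_A <= 1.0:
            raise ValueError("weight_A must be in [0, 1]")


_SIM = {"shape": similarity_shape, "elec": similarity_elec}


def _neighbour_k(n_total: int, fraction: float) -> int:
    return math.ceil(fraction * (n_total - 1))


def _distance_matrix(entries, metric: str, config: ClassifierConfig) -> np.ndarray:
    fn = _SIM[metric]
    # descriptors stored at a lower order than requested are used as-is
    triples = [t.truncate(min(config.order_max, t.order_max))
               for t in (e.triple(config.shell_fraction) for e in entries)]
    n = len(triples)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = fn(triples[i], triples[j])
    return d


def neighbor_counts(entries, metric: str,
                    config: ClassifierConfig | None = None) -> dict[str, int]:
    """Leave-one-out N_pb: protein-labelled entries among each antibody's
    k = ceil(fraction * (N - 1)) nearest neighbours (ties broken by id)."""
    config = ClassifierConfig() if config is None else config
    if metric not in _SIM:
        raise ValueError(f"metric must be one of {sorted(_SIM)}")
    ids = [e.id for e in entries]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate antibody ids")
    n = len(entries)
    k = _neighbour_k(n, config.neighbor_fraction)
    if k < 1:
        raise ValueError(f"need at least {math.ceil(1 / config.neighbor_fraction)} "
                         "entries for a non-empty neighbour set")
    d = _distance_matrix(entries, metric, config)
    is_protein = np.array([e.label == "protein" for e in entries])
    out: dict[str, int] = {}
    for i in range(n):
        others = [j for j in range(n) if j != i]
        others.sort(key=lambda j: (d[i, j], ids[j]))
        out[ids[i]] = int(is_protein[others[:k]].sum())
    return out


def combine_weighted(npb_shape, npb_elec, weight_A: float):
    """Weighted count N_pb_bar = A * N_pb_elec + (1 - A) * N_pb_shape.

    Accepts scalars or id-keyed dicts."""
    if not 0.0 <= weight_A <= 1.0:
        raise ValueError("weight A must be in [0, 1]")
    if isinstance(npb_shape, dict):
        if set(npb_shape) != set(npb_elec):
            raise ValueError("shape and elec count tables cover different ids")
        return {i: weight_A * npb_elec[i] + (1.0 - weight_A) * npb_shape[i]
                for i in npb_shape}
    return weight_A * npb_elec + (1.0 - weight_A) * npb_shape


def _expected_count(entries, k: int) -> float:
    n_prot = sum(e.label == "protein" for e in entries)
    return k * n_prot / len(entries)


def predict_labels(counts: dict[str, float], entries,
                   config: ClassifierConfig | None = None) -> dict[str, str]:
    """Label 'protein' iff N_pb strictly exceeds the uniform expectation
    Ex[N_pb] = k * N_prot / N_tot."""
    config = ClassifierConfig() if config is None else config
    k = _neighbour_k(len(entries), config.neighbor_fraction)
    threshold = _expected_count(entries, k)
    return {i: ("protein" if c > threshold else "nonprotein")
            for i, c in counts.items()}


@dataclass
class ClassificationResult:
    auc: float
    accuracy: float
    curve: pd.DataFrame
    counts: dict[str, float] = field(default_factory=dict)
    predictions: dict[str, str] = field(default_factory=dict)


def roc_analysis(counts: dict[str, float], entries,
                 config: ClassifierConfig | None = None) -> ClassificationResult:
    """ROC over the (possibly weighted) neighbour counts with 'protein' as the
    positive class, plus accuracy at the Ex[N_pb] operating point."""
    config = ClassifierConfig() if config is None else config
    labels = {e.id: e.label for e in entries}
    ids = sorted(counts)
    scores = np.array([counts[i] for i in ids])
    positive = np.array([labels[i] == "protein" for i in ids])
    auc = mann_whitney_auc(scores, positive)
    preds = predict_labels(counts, entries, config)
    accuracy = float(np.mean([preds[i] == labels[i] for i in ids]))
    return ClassificationResult(auc=auc, accuracy=accuracy,
                                curve=roc_points(scores, positive),
                                counts=dict(counts), predictions=preds)


def classify(entries, config: ClassifierConfig | None = None) -> ClassificationResult:
    """End-to-end weighted classifier at one configuration."""
    config = ClassifierConfig() if config is None else config
    npb_s = neighbor_counts(entries, "shape", config)
    npb_e = neighbor_counts(entries, "elec", config)
    combined = combine_weighted(npb_s, npb_e, config.weight_A)
    return roc_analysis(combined, entries, config)


def sweep(entries, weights=(0.0, 0.2, 0.4, 0.6, 0.8, 1.0),
          orders=(10, 15, 20), shell_fractions=(1.0,),
          neighbor_fraction: float = 0.05) -> pd.DataFrame:
    """AUC/accuracy grid over (weight A, expansion order, shell fraction).

    Descriptors are truncated from the stored order to each requested order
    (the (n, l)-lexicographic layout makes lower orders exact prefixes), so
    one descriptor computation serves the whole order grid.
    """
    rows = []
    for frac in shell_fractions:
        for order in orders:
            cfg = ClassifierConfig(neighbor_fraction=neighbor_fraction,
                                   order_max=order, shell_fraction=frac)
            npb_s = neighbor_counts(entries, "shape", cfg)
            npb_e = neighbor_counts(entries, "elec", cfg)
            for a in weights:
                res = roc_analysis(combine_weighted(npb_s, npb_e, a),
                                   entries,
                                   ClassifierConfig(neighbor_fraction=neighbor_fraction,
                                                    weight_A=a, order_max=order,
                                                    shell_fraction=frac))
                rows.append({"weight_A": a, "order": order,
                             "shell_fraction": frac, "auc": res.auc,
                             "accuracy": res.accuracy})
    return pd.DataFrame(rows)
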