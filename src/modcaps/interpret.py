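"""Source importance from routing couplings.

Each sample yields an l x k coupling matrix; averaging the (transposed)
matrices over the samples of one class gives that class's type-average
coupling matrix (k type-capsule rows, l primary-capsule columns). The row
whose type index equals the class is the "effective row": its entries score
how much each data source contributed to recognizing that class. Stacking
the effective rows of all classes gives the overall heatmap; repeat runs are
combined by element-wise averaging.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import CapsuleModel
from .sources import ModularDataset

logger = logging.getLogger(__name__)


@dataclass
class TypeAverageCoupling:
    class_index: int
    class_name: str
    matrix: np.ndarray        # (k, l): rows = type capsules, cols = primary capsules
    n_samples: int
    source_names: list[str]

    @property
    def effective_row(self) -> np.ndarray:
        return self.matrix[self.class_index]


@dataclass
class OverallHeatmap:
    matrix: np.ndarray        # (k, l)
    class_names: list[str]
    source_names: list[str]


@dataclass
class ImportanceReport:
    """Per class, the top sources ranked by averaged coupling score."""

    class_names: list[str]
    rankings: list[list[tuple[str, float]]]   # per class: (source, score) desc
    repeats: int
    k_top: int


def type_average_coupling(
    c: np.ndarray,
    labels: np.ndarray,
    class_names: list[str],
    source_names: list[str] | None = None,
) -> list[TypeAverageCoupling]:
    """Per-class element-wise mean of the samples' k x l coupling matrices.

    ``c`` has shape (n_samples, l, k) as produced by routing; each sample's
    matrix is transposed to (k, l) before averaging. Classes with zero
    samples are omitted with a warning.
    """
    c = np.asarray(c, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if c.ndim != 3 or c.shape[0] != len(labels):
        raise ValueError("couplings must be (n_samples, l, k) aligned with labels")
    n, l, k = c.shape
    if source_names is None:
        source_names = [f"source_{i}" for i in range(l)]
    out: list[TypeAverageCoupling] = []
    for t, name in enumerate(class_names):
        mask = labels == t
        if not mask.any():
            logger.warning("class %r has no samples; omitted from type averages", name)
            continue
        mean_kl = c[mask].mean(axis=0).T  # (k, l)
        out.append(TypeAverageCoupling(
            class_index=t, class_name=name, matrix=mean_kl,
            n_samples=int(mask.sum()), source_names=list(source_names),
        ))
    return out


def couplings_for_dataset(model: CapsuleModel, dataset: ModularDataset,
                          batch_size: int = 1024) -> np.ndarray:
    """Inference-mode couplings for every sample, shape (n, l, k)."""
    model.check_dataset(dataset)
    parts = []
    for start in range(0, dataset.n_samples, batch_size):
        blocks = [b[start:start + batch_size] for b in dataset.blocks]
        parts.append(model.couplings(blocks))
    return np.concatenate(parts, axis=0)


def overall_heatmap(averages: list[TypeAverageCoupling]) -> OverallHeatmap:
    """Stack each class's effective type-capsule row into a k x l matrix.

    Pure projection: row t of the result is row t of class t's average
    matrix; no values are mixed across classes.
    """
    if not averages:
        raise ValueError("no type-average matrices given")
    shapes = {a.matrix.shape for a in averages}
    if len(shapes) > 1:
        raise ValueError(f"type-average matrices disagree on shape: {sorted(shapes)}")
    source_names = averages[0].source_names
    rows = [a.effective_row for a in sorted(averages, key=lambda a: a.class_index)]
    names = [a.class_name for a in sorted(averages, key=lambda a: a.class_index)]
    return OverallHeatmap(matrix=np.vstack(rows), class_names=names,
                          source_names=list(source_names))


def average_over_repeats(heatmaps: list[OverallHeatmap]) -> OverallHeatmap:
    """Element-wise mean of repeat-run heatmaps (labels must match exactly)."""
    if not heatmaps:
        raise ValueError("no heatmaps to average")
    first = heatmaps[0]
    for h in heatmaps[1:]:
        if h.class_names != first.class_names or h.source_names != first.source_names:
            raise ValueError("heatmap label orderings differ; refusing to realign")
        if h.matrix.shape != first.matrix.shape:
            raise ValueError("heatmap shapes differ")
    mean = np.mean([h.matrix for h in heatmaps], axis=0)
    return OverallHeatmap(matrix=mean, class_names=list(first.class_names),
                          source_names=list(first.source_names))


def top_k_sources(heatmap: OverallHeatmap, k_top: int,
                  repeats: int = 1, normalize: bool = False) -> ImportanceReport:
    """Per class, the k_top highest-scoring sources (ties -> lower index first).

    With ``normalize`` each row is min-max scaled before ranking (ranks are
    unchanged; the reported scores become comparable across models).
    """
    l = heatmap.matrix.shape[1]
    if not 1 <= k_top <= l:
        raise ValueError(f"k_top must be in [1, {l}], got {k_top}")
    rankings = []
    for row in heatmap.matrix:
        scores = row.astype(np.float64)
        if normalize and np.ptp(scores) > 0:
            scores = (scores - scores.min()) / np.ptp(scores)
        order = np.argsort(-scores, kind="stable")[:k_top]
        rankings.append([(heatmap.source_names[i], float(scores[i])) for i in order])
    return ImportanceReport(class_names=list(heatmap.class_names),
                            rankings=rankings, repeats=repeats, k_top=k_top)


def heatmap_for_model(model: CapsuleModel, dataset: ModularDataset) -> OverallHeatmap:
    """Couplings -> type averages -> overall heatmap, weights frozen."""
    if dataset.labels is None:
        raise ValueError("dataset has no labels")
    c = couplings_for_dataset(model, dataset)
    averages = type_average_coupling(
        c, dataset.labels, dataset.class_names,
        source_names=dataset.source_names,
    )
    return overall_heatmap(averages)


def ranking_overlap(a: ImportanceReport, b: ImportanceReport) -> list[float]:
    """Per-class |A intersect B| / k of two top-k source sets."""
    if a.class_names != b.class_names:
        raise ValueError("reports rank different classes")
    k = min(a.k_top, b.k_top)
    out = []
    for ra, rb in zip(a.rankings, b.rankings):
        sa = {name for name, _ in ra[:k]}
        sb = {name for name, _ in rb[:k]}
        out.append(len(sa & sb) / k)
    return out
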