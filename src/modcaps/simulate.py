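"""Seeded synthetic modular datasets with known ground-truth source importance.

The generators plant a simple Gaussian mean-shift signal rather than fitting
a realistic single-cell noise model: the artifact exists to test mechanism
(can the pipeline recover which sources carry class signal?), not realism.
Expression values are rectified Gaussians so they stay non-negative without
pulling in count-model dependencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .sources import (
    GeneSet,
    GeneSetCollection,
    ModularDataset,
    SourceSpec,
    build_variant_call_spec,
)


@dataclass
class SyntheticSource:
    kind: str                          # numeric | onehot | gene_set
    length: int
    informative_for: frozenset[int] = frozenset()
    name: str | None = None


@dataclass
class SyntheticConfig:
    n_samples: int
    n_classes: int
    sources: list[SyntheticSource]
    delta: float = 2.0       # mean shift of informative features
    sigma: float = 1.0       # noise scale
    onehot_p: float = 0.9    # probability the class-linked category fires
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_samples < self.n_classes:
            problems.append("need at least one sample per class")
        if self.n_classes < 1:
            problems.append("n_classes must be >= 1")
        if not self.sources:
            problems.append("at least one source required")
        for i, s in enumerate(self.sources):
            if s.length < 1:
                problems.append(f"source {i}: length must be >= 1")
            if s.kind not in ("numeric", "onehot", "gene_set"):
                problems.append(f"source {i}: unknown kind {s.kind!r}")
            bad = [t for t in s.informative_for if not 0 <= t < self.n_classes]
            if bad:
                problems.append(f"source {i}: informative_for references classes {bad}")
        if self.delta != 0:
            covered = set().union(*(s.informative_for for s in self.sources)) \
                if self.sources else set()
            if covered and covered != set(range(self.n_classes)):
                missing = sorted(set(range(self.n_classes)) - covered)
                if missing:
                    problems.append(f"classes {missing} have no informative source")
        if self.n_classes > 1 and not (1.0 / self.n_classes < self.onehot_p <= 1.0):
            problems.append(f"onehot_p must be in (1/k, 1], got {self.onehot_p}")
        if problems:
            raise ValueError("invalid synthetic config: " + "; ".join(problems))


@dataclass
class GroundTruth:
    """Which (class, source) pairs carry planted signal, and the shift size."""

    informative: np.ndarray            # (k, l) boolean
    shifts: list[np.ndarray] = field(default_factory=list)  # per source, per feature
    relevant_sets: dict[int, list[str]] = field(default_factory=dict)

    def informative_sources(self, cls: int) -> list[int]:
        return list(np.flatnonzero(self.informative[cls]))


def _balanced_labels(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    labels = np.arange(n) % k
    return labels[rng.permutation(n)]


def generate_modular(cfg: SyntheticConfig) -> tuple[ModularDataset, GroundTruth]:
    """Generate a labeled multi-source dataset with planted class signal.

    Numeric/gene_set blocks are Normal(0, sigma^2) noise; features of a
    source informative for class t gain a +delta mean for samples of class t.
    One-hot blocks fire category (class mod length) with probability
    ``onehot_p`` (else a uniformly random other category); non-informative
    one-hot blocks fire a uniformly random category. Labels are balanced to
    within one sample. Fully determined by ``cfg.seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n, k = cfg.n_samples, cfg.n_classes
    labels = _balanced_labels(n, k, rng)

    specs: list[SourceSpec] = []
    blocks: list[np.ndarray] = []
    informative = np.zeros((k, len(cfg.sources)), dtype=bool)
    shifts: list[np.ndarray] = []
    for i, src in enumerate(cfg.sources):
        name = src.name or f"source_{i}"
        feats = tuple(f"{name}_f{j}" for j in range(src.length))
        specs.append(SourceSpec(name=name, kind=src.kind, features=feats))
        if cfg.delta != 0:
            for t in src.informative_for:
                informative[t, i] = True
        if src.kind == "onehot":
            block = np.zeros((n, src.length))
            if src.informative_for:
                linked = labels % src.length
                fire = rng.random(n) < cfg.onehot_p
                other = rng.integers(0, src.length - 1, size=n) if src.length > 1 \
                    else np.zeros(n, dtype=int)
                other = np.where(other >= linked, other + 1, other) if src.length > 1 else other
                cat = np.where(fire, linked, other)
            else:
                cat = rng.integers(0, src.length, size=n)
            block[np.arange(n), cat] = 1.0
            shifts.append(np.zeros(src.length))
        else:
            block = rng.normal(0.0, cfg.sigma, size=(n, src.length))
            shift = np.full(src.length, cfg.delta)
            for t in src.informative_for:
                block[labels == t] += shift
            shifts.append(shift if src.informative_for else np.zeros(src.length))
        blocks.append(block)

    dataset = ModularDataset(
        sources=specs, blocks=blocks, labels=labels,
        class_names=[f"class_{t}" for t in range(k)],
    )
    return dataset, GroundTruth(informative=informative, shifts=shifts)


def variant_call_like_config(n_samples: int = 3000, seed: int = 0,
                             delta: float = 2.0) -> SyntheticConfig:
    """A config mirroring the packaged 8-group / 71-feature layout, 3 classes."""
    specs = build_variant_call_spec()
    k = 3
    sources = []
    for i, s in enumerate(specs):
        informative = frozenset({i % k}) if s.kind == "numeric" else frozenset()
        sources.append(SyntheticSource(kind=s.kind, length=s.length,
                                       informative_for=informative, name=s.name))
    return SyntheticConfig(n_samples=n_samples, n_classes=k, sources=sources,
                           delta=delta, seed=seed)


def planted_importance_config(
    n_samples: int = 2000,
    n_classes: int = 5,
    n_sources: int = 10,
    source_length: int = 5,
    delta: float = 2.0,
    sigma: float = 1.0,
    seed: int = 0,
) -> SyntheticConfig:
    """The parameter-recovery fixture: each class gets exactly
    ``n_sources // n_classes`` informative sources, assigned round-robin."""
    if n_sources % n_classes != 0:
        raise ValueError("n_sources must be a multiple of n_classes")
    sources = [
        SyntheticSource(kind="numeric", length=source_length,
                        informative_for=frozenset({i % n_classes}))
        for i in range(n_sources)
    ]
    return SyntheticConfig(n_samples=n_samples, n_classes=n_classes,
                           sources=sources, delta=delta, sigma=sigma, seed=seed)


# ---------------------------------------------------------------------------
# Expression matrix + gene sets
# ---------------------------------------------------------------------------

def generate_expression_with_sets(
    n_genes: int = 500,
    n_sets: int = 60,
    genes_per_set: int = 8,
    overlap_fraction: float = 0.25,
    n_samples: int = 2000,
    n_classes: int = 7,
    delta: float = 2.0,
    sigma: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, GeneSetCollection, np.ndarray, GroundTruth]:
    """Generate a samples x genes expression matrix plus planted gene sets.

    Each set draws ``overlap_fraction`` of its genes from previously used
    genes and the rest from fresh ones, so sets overlap by construction
    (``overlap_fraction=0`` gives pairwise-disjoint sets). Set j is
    "relevant" for class ``j mod n_classes``: its member genes are up-shifted
    by delta in samples of that class. Expression is ``max(0, Normal)``.
    """
    n_fresh = genes_per_set - int(round(overlap_fraction * genes_per_set))
    if n_sets * n_fresh > n_genes:
        raise ValueError(
            f"infeasible overlap: {n_sets} sets x {n_fresh} fresh genes "
            f"exceed {n_genes} genes"
        )
    rng = np.random.default_rng(seed)
    genes = [f"g{j:04d}" for j in range(n_genes)]
    labels = _balanced_labels(n_samples, n_classes, rng)

    used: list[str] = []
    unused = list(genes)
    members: list[list[str]] = []
    for _ in range(n_sets):
        n_old = min(genes_per_set - n_fresh, len(used))
        chosen = list(rng.choice(used, size=n_old, replace=False)) if n_old else []
        fresh_idx = rng.choice(len(unused), size=n_fresh, replace=False)
        fresh = [unused[i] for i in sorted(fresh_idx)]
        for g in fresh:
            unused.remove(g)
            used.append(g)
        members.append(chosen + fresh)

    expr = rng.normal(0.0, sigma, size=(n_samples, n_genes))
    gene_idx = {g: j for j, g in enumerate(genes)}
    informative = np.zeros((n_classes, n_sets), dtype=bool)
    relevant: dict[int, list[str]] = {t: [] for t in range(n_classes)}
    set_labels = [f"SET{j:03d}" for j in range(n_sets)]
    for j, genes_j in enumerate(members):
        t = j % n_classes
        informative[t, j] = True
        relevant[t].append(set_labels[j])
        cols = [gene_idx[g] for g in genes_j]
        expr[np.ix_(labels == t, cols)] += delta
    expr = np.maximum(expr, 0.0)

    collection = GeneSetCollection(sets=tuple(
        GeneSet(label=lab, category="regulon", genes=tuple(gs))
        for lab, gs in zip(set_labels, members)
    ))
    truth = GroundTruth(informative=informative, relevant_sets=relevant)
    frame = pd.DataFrame(expr, columns=genes,
                         index=[f"cell_{i}" for i in range(n_samples)])
    return frame, collection, labels, truth
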