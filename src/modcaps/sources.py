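"""Modular data sources: specs, gene-set priors, and expression decomposition.

A "source" is one block of input features that feeds a single per-source
encoder. Sources are either native (numeric / one-hot columns of a tabular
dataset) or derived by slicing a gene-expression matrix with prior-knowledge
gene sets (TF target lists, PPI subnetworks, regulons).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SOURCE_KINDS = ("numeric", "onehot", "gene_set")
GENE_SET_CATEGORIES = ("TF", "PPI", "regulon")


@dataclass(frozen=True)
class SourceSpec:
    """One modular input source: a named, ordered group of features."""

    name: str
    kind: str
    features: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.kind not in SOURCE_KINDS:
            raise ValueError(
                f"source {self.name!r}: kind must be one of {SOURCE_KINDS}, got {self.kind!r}"
            )
        if len(self.features) == 0:
            raise ValueError(f"source {self.name!r}: feature list is empty")
        if len(set(self.features)) != len(self.features):
            raise ValueError(f"source {self.name!r}: duplicate feature identifiers")
        object.__setattr__(self, "features", tuple(self.features))

    @property
    def length(self) -> int:
        """Number of features r_i in this source."""
        return len(self.features)


@dataclass(frozen=True)
class GeneSet:
    label: str
    category: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.category not in GENE_SET_CATEGORIES:
            raise ValueError(
                f"gene set {self.label!r}: category must be one of "
                f"{GENE_SET_CATEGORIES}, got {self.category!r}"
            )
        if len(self.genes) == 0:
            raise ValueError(f"gene set {self.label!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.label!r}: duplicate gene symbols")
        object.__setattr__(self, "genes", tuple(self.genes))


@dataclass(frozen=True)
class GeneSetCollection:
    """An ordered collection of (possibly overlapping) gene sets."""

    sets: tuple[GeneSet, ...]

    def __post_init__(self) -> None:
        labels = [s.label for s in self.sets]
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise ValueError(f"duplicate gene set labels: {dupes}")
        object.__setattr__(self, "sets", tuple(self.sets))

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, label: str) -> GeneSet:
        for s in self.sets:
            if s.label == label:
                return s
        raise KeyError(label)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(s.label for s in self.sets)

    @property
    def universe(self) -> tuple[str, ...]:
        """Sorted union of all gene symbols across sets."""
        return tuple(sorted({g for s in self.sets for g in s.genes}))


@dataclass
class ModularDataset:
    """Row-aligned per-source blocks plus (optional) integer class labels."""

    sources: list[SourceSpec]
    blocks: list[np.ndarray]
    labels: np.ndarray | None = None
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.sources) < 1:
            raise ValueError("a modular dataset needs at least one source")
        if len(self.sources) != len(self.blocks):
            raise ValueError(
                f"{len(self.sources)} sources but {len(self.blocks)} blocks"
            )
        names = [s.name for s in self.sources]
        if len(set(names)) != len(names):
            raise ValueError("source names must be unique within a dataset")
        n_rows = {b.shape[0] for b in self.blocks}
        if len(n_rows) > 1:
            raise ValueError(f"blocks disagree on sample count: {sorted(n_rows)}")
        for spec, block in zip(self.sources, self.blocks):
            if block.ndim != 2 or block.shape[1] != spec.length:
                raise ValueError(
                    f"block for source {spec.name!r} has shape {block.shape}, "
                    f"expected (*, {spec.length})"
                )
        self.blocks = [np.asarray(b, dtype=np.float64) for b in self.blocks]
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)
            if self.labels.shape != (self.n_samples,):
                raise ValueError("labels must be one integer per sample")
            if self.class_names:
                k = len(self.class_names)
                if self.labels.min(initial=0) < 0 or self.labels.max(initial=0) >= k:
                    raise ValueError(
                        f"labels reference classes outside [0, {k})"
                    )

    @property
    def n_samples(self) -> int:
        return self.blocks[0].shape[0]

    @property
    def n_sources(self) -> int:
        return len(self.sources)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    @property
    def source_names(self) -> list[str]:
        return [s.name for s in self.sources]

    def subset(self, idx: np.ndarray) -> "ModularDataset":
        return ModularDataset(
            sources=list(self.sources),
            blocks=[b[idx] for b in self.blocks],
            labels=None if self.labels is None else self.labels[idx],
            class_names=list(self.class_names),
        )

    def with_labels(self, labels: np.ndarray, class_names: Sequence[str]) -> "ModularDataset":
        return ModularDataset(
            sources=list(self.sources),
            blocks=list(self.blocks),
            labels=np.asarray(labels),
            class_names=list(class_names),
        )


# ---------------------------------------------------------------------------
# Packaged variant-call layout
# ---------------------------------------------------------------------------

def _load_packaged_manifest() -> dict:
    text = resources.files("modcaps").joinpath("data/variant_call_manifest.json").read_text()
    return json.loads(text)


def build_variant_call_spec() -> list[SourceSpec]:
    """Return the packaged eight-group / 71-feature variant-call source layout.

    Groups, in order: Disease (one-hot, 9), Reviewer (one-hot, 4),
    Normal_pro (3), Normal_ref (13), Normal_var (13), Tumor_pro (3),
    Tumor_ref (13), Tumor_var (13).
    """
    manifest = _load_packaged_manifest()
    return [
        SourceSpec(name=g["name"], kind=g["kind"], features=tuple(g["features"]))
        for g in manifest["groups"]
    ]


# ---------------------------------------------------------------------------
# Gene-set parsing
# ---------------------------------------------------------------------------

def parse_gene_sets(
    path: str | Path,
    category_rule: Mapping[str, str] | None = None,
    default_category: str = "regulon",
) -> GeneSetCollection:
    """Parse a GMT or two-column (label<TAB>gene) gene-set file.

    GMT lines are ``label<TAB>description<TAB>gene...``; any line with three
    or more tab-separated fields is treated as GMT, two-field lines as long
    format. Gene order within a set follows first occurrence; duplicate
    (label, gene) pairs collapse to one membership.

    Parameters
    ----------
    category_rule
        Optional mapping from set label to category (``TF``/``PPI``/
        ``regulon``); unlisted labels fall back to *default_category*.
    """
    path = Path(path)
    rows: list[tuple[int, list[str]]] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if lineno == 1 and len(fields) == 2 and fields[0].lower() in ("label", "set", "tf") \
                and fields[1].lower() in ("gene", "target", "member"):
            continue  # optional header of the long format
        rows.append((lineno, fields))
    # dialect is a property of the file: any >= 3-field line means GMT,
    # where field 2 is a description, not a gene
    is_gmt = any(len(fields) >= 3 for _, fields in rows)
    order: list[str] = []
    members: dict[str, list[str]] = {}
    seen: dict[str, set[str]] = {}
    n_data_lines = 0
    for lineno, fields in rows:
        n_data_lines += 1
        label = fields[0]
        if is_gmt:
            genes = [g for g in fields[2:] if g]
        else:
            genes = [fields[1]] if len(fields) == 2 and fields[1] else []
        if not label:
            raise ValueError(f"{path}:{lineno}: line has no set label")
        if not genes:
            raise ValueError(f"{path}:{lineno}: set {label!r} declares zero genes")
        if label not in members:
            order.append(label)
            members[label] = []
            seen[label] = set()
        for g in genes:
            if g not in seen[label]:
                seen[label].add(g)
                members[label].append(g)
    if n_data_lines == 0:
        raise ValueError(f"{path}: no gene sets")
    rule = dict(category_rule or {})
    sets = tuple(
        GeneSet(label=lab, category=rule.get(lab, default_category), genes=tuple(members[lab]))
        for lab in order
    )
    return GeneSetCollection(sets=sets)


def write_gmt(sets: GeneSetCollection, path: str | Path, description: str = ".") -> None:
    """Write a collection as a GMT file (inverse of :func:`parse_gene_sets`)."""
    lines = [
        "\t".join([s.label, description, *s.genes]) for s in sets
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Expression decomposition
# ---------------------------------------------------------------------------

def decompose_expression(
    matrix: pd.DataFrame,
    sets: GeneSetCollection,
) -> ModularDataset:
    """Slice a samples x genes matrix into one block per gene set.

    Each block's columns follow the set's own gene order. A gene absent from
    the matrix contributes a column of zeros; a gene present in several sets
    is copied into every containing block. Labels are left unset.
    """
    if len(sets) == 0:
        raise ValueError("gene set collection is empty")
    col_index = {g: i for i, g in enumerate(matrix.columns)}
    values = matrix.to_numpy(dtype=np.float64)
    n = values.shape[0]
    specs: list[SourceSpec] = []
    blocks: list[np.ndarray] = []
    for s in sets:
        block = np.zeros((n, len(s.genes)), dtype=np.float64)
        hit = 0
        for j, g in enumerate(s.genes):
            i = col_index.get(g)
            if i is not None:
                block[:, j] = values[:, i]
                hit += 1
        if hit == 0:
            logger.warning(
                "gene set %r: none of its %d genes are in the expression matrix; "
                "its block is all zeros", s.label, len(s.genes)
            )
        specs.append(SourceSpec(name=s.label, kind="gene_set", features=s.genes))
        blocks.append(block)
    return ModularDataset(sources=specs, blocks=blocks)


def exclude_labeling_tf(sets: GeneSetCollection) -> GeneSetCollection:
    """Remove each set's own label symbol from its gene list.

    Sets that become empty after removal are dropped with a warning; sets not
    containing their label pass through untouched. Idempotent.
    """
    kept: list[GeneSet] = []
    for s in sets:
        if s.label in s.genes:
            genes = tuple(g for g in s.genes if g != s.label)
            if not genes:
                logger.warning(
                    "gene set %r contained only its labeling TF; dropped", s.label
                )
                continue
            kept.append(replace(s, genes=genes))
        else:
            kept.append(s)
    return GeneSetCollection(sets=tuple(kept))
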