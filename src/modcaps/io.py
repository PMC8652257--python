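"""Readers and writers for the on-disk formats: expression matrices
(delimited or Matrix Market + sidecars), modular-dataset manifests, and the
TSV/JSON result files."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.io import mmread

from .interpret import ImportanceReport, OverallHeatmap, TypeAverageCoupling
from .sources import ModularDataset, SourceSpec
from .train import EvalReport, History


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

def load_expression(
    path: str | Path,
    transpose: bool = False,
    row_names: str | Path | None = None,
    col_names: str | Path | None = None,
    sep: str = "\t",
) -> pd.DataFrame:
    """Load a samples x genes expression matrix.

    Delimited text is read with the first column as row index and the header
    as gene names. ``.mtx`` input requires ``row_names``/``col_names``
    sidecar files (one name per line). ``transpose`` flips a genes x samples
    layout into samples x genes after loading.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"expression file not found: {path}")
    if path.suffix == ".mtx":
        if row_names is None or col_names is None:
            raise ValueError(".mtx input needs row_names and col_names sidecar files")
        raw = mmread(str(path))
        mat = np.asarray(raw.todense() if hasattr(raw, "todense") else raw)
        rows = Path(row_names).read_text().split()
        cols = Path(col_names).read_text().split()
        frame = pd.DataFrame(mat, index=rows, columns=cols)
    else:
        frame = pd.read_csv(path, sep=sep, index_col=0)
    if transpose:
        frame = frame.T
    return frame


def load_labels(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Load per-sample class labels from a one- or two-column file.

    Two columns = (sample id, label); one column = labels in row order.
    String labels are mapped to indices in order of first appearance.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"label file not found: {path}")
    frame = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    col = frame.iloc[:, 1] if frame.shape[1] >= 2 else frame.iloc[:, 0]
    if str(col.iloc[0]).lower() in ("label", "class", "cell_type"):
        col = col.iloc[1:]
    names: list[str] = []
    index: dict[str, int] = {}
    out = []
    for value in col:
        if value not in index:
            index[value] = len(names)
            names.append(value)
        out.append(index[value])
    return np.array(out, dtype=np.int64), names


# ---------------------------------------------------------------------------
# Modular manifests
# ---------------------------------------------------------------------------

def load_modular_manifest(path: str | Path) -> ModularDataset:
    """Load a modular dataset described by a YAML/JSON manifest.

    Schema::

        labels: labels.tsv           # optional
        sources:
          - {name: Disease, kind: onehot, file: disease.tsv}
          - ...

    Each source file is a TSV with a header row of feature names; rows are
    samples, aligned across all source files.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    text = path.read_text()
    manifest = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    base = path.parent
    specs: list[SourceSpec] = []
    blocks: list[np.ndarray] = []
    for entry in manifest["sources"]:
        fpath = base / entry["file"]
        if not fpath.exists():
            raise FileNotFoundError(f"source file not found: {fpath}")
        frame = pd.read_csv(fpath, sep="\t")
        specs.append(SourceSpec(name=entry["name"], kind=entry["kind"],
                                features=tuple(frame.columns)))
        blocks.append(frame.to_numpy(dtype=np.float64))
    labels = class_names = None
    if manifest.get("labels"):
        labels, seen_names = load_labels(base / manifest["labels"])
        class_names = manifest.get("class_names") or seen_names
        if class_names is not seen_names:
            remap = {name: class_names.index(name) for name in seen_names}
            labels = np.array([remap[seen_names[t]] for t in labels])
    return ModularDataset(sources=specs, blocks=blocks, labels=labels,
                          class_names=class_names or [])


def write_modular_dataset(dataset: ModularDataset, outdir: str | Path) -> Path:
    """Write per-source TSVs, labels and a YAML manifest; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for spec, block in zip(dataset.sources, dataset.blocks):
        fname = f"{spec.name}.tsv"
        pd.DataFrame(block, columns=list(spec.features)).to_csv(
            outdir / fname, sep="\t", index=False)
        entries.append({"name": spec.name, "kind": spec.kind, "file": fname})
    manifest: dict = {"sources": entries}
    if dataset.labels is not None:
        lines = [dataset.class_names[t] if dataset.class_names else str(t)
                 for t in dataset.labels]
        (outdir / "labels.tsv").write_text("\n".join(lines) + "\n")
        manifest["labels"] = "labels.tsv"
        if dataset.class_names:
            manifest["class_names"] = list(dataset.class_names)
    manifest_path = outdir / "manifest.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return manifest_path


# ---------------------------------------------------------------------------
# Result serialization
# ---------------------------------------------------------------------------

def write_history(history: History, path: str | Path) -> None:
    pd.DataFrame({
        "epoch": history.epoch,
        "train_loss": history.train_loss,
        "val_accuracy": history.val_accuracy,
    }).to_csv(path, sep="\t", index=False)


def write_eval_report(report: EvalReport, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2) + "\n")


def write_heatmap(heatmap: OverallHeatmap, path: str | Path) -> None:
    pd.DataFrame(heatmap.matrix, index=heatmap.class_names,
                 columns=heatmap.source_names).to_csv(path, sep="\t",
                                                      index_label="class")


def read_heatmap(path: str | Path) -> OverallHeatmap:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return OverallHeatmap(matrix=frame.to_numpy(dtype=np.float64),
                          class_names=list(frame.index),
                          source_names=list(frame.columns))


def write_type_averages(averages: list[TypeAverageCoupling],
                        outdir: str | Path) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for avg in averages:
        p = outdir / f"type_average_{avg.class_name}.tsv"
        pd.DataFrame(avg.matrix, columns=avg.source_names).to_csv(
            p, sep="\t", index_label="type_capsule")
        paths.append(p)
    return paths


def write_importance_report(report: ImportanceReport, path: str | Path) -> None:
    rows = []
    for cls, ranking in zip(report.class_names, report.rankings):
        for rank, (source, score) in enumerate(ranking, start=1):
            rows.append({"class": cls, "rank": rank, "source": source,
                         "score": score})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
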