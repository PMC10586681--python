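"""Readers and writers for the pipeline's file formats.

Responses travel as UTF-8 delimited text (CSV or TSV), one row per
participant with positional columns ``assoc_1..assoc_5`` and
``emo_1a..emo_5b``.  Networks are exported as GraphML plus a weighted
edge list; partitions and profiles as JSON.  All writer/reader pairs are
exact inverses on valid data.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd

from .datatypes import (
    ALL_CATEGORIES,
    EMOTION_LABELS,
    N_ASSOCIATIONS,
    Corpus,
    FormatError,
    MergeMap,
    PipelineConfig,
    ResponseRecord,
    ValidationError,
)

__all__ = [
    "RESPONSE_COLUMNS",
    "read_responses",
    "write_responses",
    "read_merge_map",
    "write_network",
    "read_network",
    "write_partition",
    "read_partition",
]


def _response_columns() -> list[str]:
    cols = ["participant_id"]
    cols += [f"assoc_{k}" for k in range(1, N_ASSOCIATIONS + 1)]
    for k in range(1, N_ASSOCIATIONS + 1):
        cols += [f"emo_{k}a", f"emo_{k}b"]
    cols += ["category", "intensity"]
    return cols


RESPONSE_COLUMNS = _response_columns()


def read_responses(
    path: str | Path,
    config: PipelineConfig | None = None,
    sep: str | None = None,
    require_full_arity: bool = True,
) -> Corpus:
    """Read a participant-response table into a validated :class:`Corpus`.

    Rows violating the record invariants (wrong arity, unknown labels or
    categories, out-of-range intensity) are rejected collectively with a
    diagnostic naming every offending participant.  ``sep=None``
    auto-detects comma vs. tab from the file extension.  Raw survey
    tables must carry exactly five associations per row; pass
    ``require_full_arity=False`` to re-read corpora already reduced by
    the rare-token filter.
    """
    path = Path(path)
    config = config or PipelineConfig()
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in RESPONSE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")

    records: list[ResponseRecord] = []
    problems: list[str] = []
    for _, row in df.iterrows():
        pid = row["participant_id"]
        assocs = tuple(
            row[f"assoc_{k}"].strip()
            for k in range(1, N_ASSOCIATIONS + 1)
            if row[f"assoc_{k}"].strip()
        )
        labels = tuple(
            (row[f"emo_{k}a"].strip(), row[f"emo_{k}b"].strip())
            for k in range(1, N_ASSOCIATIONS + 1)
            if row[f"assoc_{k}"].strip()
        )
        try:
            intensity = int(row["intensity"])
        except ValueError:
            problems.append(f"{pid}: non-integer intensity {row['intensity']!r}")
            continue
        rec = ResponseRecord(
            participant_id=pid,
            associations=assocs,
            emotion_labels=labels,
            category=row["category"].strip(),
            intensity_raw=intensity,
        )
        try:
            rec.validate(label_list=config.label_list, require_full_arity=require_full_arity)
        except ValidationError as exc:
            problems.append(str(exc))
            continue
        records.append(rec)
    if problems:
        raise ValidationError(
            "invalid response rows:\n  " + "\n  ".join(problems)
        )
    return Corpus(records=records, label_list=config.label_list)


def write_responses(corpus: Corpus, path: str | Path, sep: str | None = None) -> None:
    """Write a corpus back to the delimited response format.

    Records filtered below full arity are padded with empty cells so the
    positional layout is preserved; :func:`read_responses` skips empty
    association cells, making write→read the identity on any corpus.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    rows = []
    for rec in corpus.records:
        row: dict[str, object] = {"participant_id": rec.participant_id}
        for k in range(1, N_ASSOCIATIONS + 1):
            if k <= len(rec.associations):
                row[f"assoc_{k}"] = rec.associations[k - 1]
                row[f"emo_{k}a"], row[f"emo_{k}b"] = rec.emotion_labels[k - 1]
            else:
                row[f"assoc_{k}"] = row[f"emo_{k}a"] = row[f"emo_{k}b"] = ""
        row["category"] = rec.category
        row["intensity"] = rec.intensity_raw
        rows.append(row)
    pd.DataFrame(rows, columns=RESPONSE_COLUMNS).to_csv(path, sep=sep, index=False)


def read_merge_map(path: str | Path) -> MergeMap:
    """Read a two-column (raw, canonical) CSV/TSV merge map."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: merge map needs two columns (raw, canonical)")
    raw_col, canon_col = df.columns[:2]
    return MergeMap(dict(zip(df[raw_col], df[canon_col])))


# ---------------------------------------------------------------------------
# network export


def _to_graph(net, partition=None) -> nx.Graph:
    g = nx.Graph()
    module_of = dict(partition.membership) if partition is not None else {}
    if partition is not None:
        missing = set(net.nodes) - set(module_of)
        if missing:
            raise ValidationError(
                f"partition does not cover nodes: {sorted(missing)[:5]}..."
            )
    for tok in net.nodes:
        attrs = {"frequency": int(net.frequencies[tok])}
        if partition is not None:
            attrs["module"] = int(module_of[tok])
        g.add_node(tok, **attrs)
    for (u, v), w in net.edges.items():
        g.add_edge(u, v, weight=float(w))
    return g


def write_network(net, path: str | Path, partition=None) -> None:
    """Export a signed network as GraphML plus a plain weighted edge list.

    ``path`` names the GraphML file; an edge-list variant with the same
    stem and suffix ``.edges.tsv`` is written alongside.  Node attributes:
    token (id), participant frequency, and module id when a partition is
    given.  Edge attribute: the signed weight at full float precision.
    """
    path = Path(path)
    g = _to_graph(net, partition)
    nx.write_graphml(g, path, infer_numeric_types=False)
    edge_path = path.with_suffix(".edges.tsv")
    with open(edge_path, "w", encoding="utf-8") as fh:
        fh.write("source\ttarget\tweight\n")
        for (u, v), w in sorted(net.edges.items()):
            fh.write(f"{u}\t{v}\t{w!r}\n")


def read_network(path: str | Path):
    """Read a GraphML file written by :func:`write_network` back exactly."""
    from .cooccurrence import SignedNetwork

    g = nx.read_graphml(Path(path))
    nodes = tuple(sorted(g.nodes))
    freqs = {n: int(g.nodes[n]["frequency"]) for n in nodes}
    edges = {}
    for u, v, data in g.edges(data=True):
        key = (u, v) if u < v else (v, u)
        edges[key] = float(data["weight"])
    return SignedNetwork(nodes=nodes, frequencies=freqs, edges=edges)


def write_partition(partition, path: str | Path, extra: dict | None = None) -> None:
    payload = {
        "n_modules": partition.n_modules,
        "membership": {node: int(m) for node, m in sorted(partition.membership.items())},
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_partition(path: str | Path):
    from .community import Partition

    payload = json.loads(Path(path).read_text())
    return Partition(membership=dict(payload["membership"]))
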