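"""Tab-delimited readers/writers and provenance headers shared by the CLI.

All matrices and tables are TSV; small model metadata is JSON. Every writer
prepends ``#``-prefixed provenance lines (tool version, parameters, seed,
input checksums) which every reader skips.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import pandas as pd

from . import __version__
from .pathway_db import Subnetwork, SubnetworkDB, _edge
from .scoring import SubnetworkWeights

__all__ = [
    "provenance_header",
    "file_checksum",
    "write_subnetwork_db",
    "read_subnetwork_db",
    "write_weights",
    "read_weights",
    "write_risk_matrix",
    "read_risk_matrix",
]


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def provenance_header(command: str, params: dict,
                      inputs: list[str | Path] = ()) -> str:
    lines = [f"# simms {__version__} :: {command}"]
    for k in sorted(params):
        lines.append(f"# param {k}={params[k]}")
    for p in inputs:
        lines.append(f"# input {Path(p).name} sha256:{file_checksum(p)}")
    return "\n".join(lines) + "\n"


def _write_tsv(df: pd.DataFrame, path: str | Path, header: str,
               index_label: str | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=index_label is not None,
                  index_label=index_label)


def write_subnetwork_db(db: SubnetworkDB, path: str | Path,
                        header: str = "") -> None:
    rows = []
    for sn in db:
        for node in sorted(sn.nodes):
            rows.append((sn.subnetwork_id, sn.pathway_id, "node", node))
        for a, b in sorted(sn.edges):
            rows.append((sn.subnetwork_id, sn.pathway_id, "edge", f"{a}|{b}"))
    df = pd.DataFrame(rows, columns=["subnetwork_id", "pathway_id",
                                     "element_type", "element"])
    _write_tsv(df, path, header)


def read_subnetwork_db(path: str | Path) -> SubnetworkDB:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    subnetworks = []
    for (sid, pid), grp in df.groupby(["subnetwork_id", "pathway_id"],
                                      sort=True):
        nodes = set(grp.loc[grp["element_type"] == "node", "element"])
        edges = set()
        for el in grp.loc[grp["element_type"] == "edge", "element"]:
            a, _, b = el.partition("|")
            edges.add(_edge(a, b))
        subnetworks.append(Subnetwork(sid, pid, frozenset(nodes),
                                      frozenset(edges)))
    return SubnetworkDB(subnetworks, provenance={"source": str(path)})


def write_weights(weights: dict[str, SubnetworkWeights], path: str | Path,
                  header: str = "") -> None:
    rows = []
    for sid in sorted(weights):
        w = weights[sid]
        for g in sorted(w.node_weights):
            l2, p = w.node_weights[g]
            rows.append((sid, "node", g, l2, p))
        for e in sorted(w.edge_weights):
            l2, p = w.edge_weights[e]
            rows.append((sid, "edge", f"{e[0]}|{e[1]}", l2, p))
        for g in sorted(w.node_medians):
            # frozen training dichotomization threshold; value in log2_hr col
            rows.append((sid, "threshold", g, w.node_medians[g], ""))
    df = pd.DataFrame(rows, columns=["subnetwork_id", "element_type",
                                     "element", "log2_hr", "wald_p"])
    _write_tsv(df, path, header)


def read_weights(path: str | Path) -> dict[str, SubnetworkWeights]:
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"subnetwork_id": str, "element_type": str,
                            "element": str})
    out: dict[str, SubnetworkWeights] = {}
    for sid, grp in df.groupby("subnetwork_id", sort=True):
        w = SubnetworkWeights(str(sid))
        for _, row in grp.iterrows():
            kind, el = row["element_type"], row["element"]
            if kind == "node":
                w.node_weights[el] = (float(row["log2_hr"]),
                                      float(row["wald_p"]))
            elif kind == "edge":
                a, _, b = el.partition("|")
                w.edge_weights[_edge(a, b)] = (float(row["log2_hr"]),
                                               float(row["wald_p"]))
            elif kind == "threshold":
                w.node_medians[el] = float(row["log2_hr"])
            else:
                raise ValueError(f"{path}: unknown element_type {kind!r}")
        out[str(sid)] = w
    return out


def write_risk_matrix(risk: pd.DataFrame, path: str | Path,
                      header: str = "") -> None:
    _write_tsv(risk, path, header, index_label="sample_id")


def read_risk_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col="sample_id")
    df.index = df.index.astype(str)
    return df.astype(float)
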