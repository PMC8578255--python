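"""Readers and writers for the interchange formats.

Edge lists are two- or three-column TSV (gene_a, gene_b[, weight]) with
'#'-prefixed comments; multiplex manifests are JSON listing layer name, scale
and file path; gene sets use GMT; ontologies a minimal OBO subset ([Term]
stanzas with id/name/is_a, obsolete stanzas skipped); annotations and
expression matrices are TSV.  Readers log counts of records read and skipped
to the module logger; every reader/writer pair round-trips canonical forms.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .builders import ExpressionMatrix
from .modules import DiseaseGroup
from .multiplex import Layer, MultiplexNetwork, canonical_edge
from .ontology import AnnotationTable, Ontology
from .simulate import PatientCase

logger = logging.getLogger("plexprop")

__all__ = [
    "read_edge_list",
    "write_edge_list",
    "read_multiplex",
    "write_multiplex",
    "read_gene_sets",
    "write_gene_sets",
    "read_obo_lite",
    "write_obo_lite",
    "read_annotations",
    "write_annotations",
    "read_expression",
    "write_expression",
    "read_patient_case",
    "write_patient_case",
]

FLOAT_FMT = "{:.10g}"  # 10 significant digits keeps determinism checks meaningful


def read_edge_list(
    path: str | Path, name: str | None = None, scale: str = "other", header: bool = False
) -> Layer:
    """Parse a TSV edge list into a Layer.

    Mixed 2- and 3-column rows or conflicting duplicate weights are errors
    (reported with line numbers); self-loops are dropped with a warning.
    """
    path = Path(path)
    edges: set[tuple[str, str]] = set()
    weights: dict[tuple[str, str], float] = {}
    n_cols: int | None = None
    n_loops = 0
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if header:
                header = False
                continue
            parts = line.split("\t")
            if len(parts) not in (2, 3):
                raise ValueError(f"{path}:{lineno}: expected 2 or 3 columns, got {len(parts)}")
            if n_cols is None:
                n_cols = len(parts)
            elif len(parts) != n_cols:
                raise ValueError(f"{path}:{lineno}: mixed column counts ({len(parts)} vs {n_cols})")
            u, v = parts[0], parts[1]
            if u == v:
                n_loops += 1
                continue
            e = canonical_edge(u, v)
            if len(parts) == 3:
                try:
                    w = float(parts[2])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: bad weight {parts[2]!r}") from exc
                if e in weights and not np.isclose(weights[e], w):
                    raise ValueError(f"{path}:{lineno}: conflicting weights for edge {e}")
                weights[e] = w
            edges.add(e)
    if n_loops:
        logger.warning("%s: dropped %d self-loop(s)", path, n_loops)
    logger.info("%s: read %d edges", path, len(edges))
    return Layer(
        name or path.stem, edges, weights=weights if n_cols == 3 else None, scale=scale
    )


def write_edge_list(layer: Layer, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for u, v in sorted(layer.edges):
            if layer.weighted:
                fh.write(f"{u}\t{v}\t{FLOAT_FMT.format(layer.weights[(u, v)])}\n")
            else:
                fh.write(f"{u}\t{v}\n")


def read_multiplex(manifest_path: str | Path) -> MultiplexNetwork:
    """Load a multiplex from a JSON manifest of {name, scale, path} entries."""
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    layers = [
        read_edge_list(
            manifest_path.parent / entry["path"],
            name=entry["name"],
            scale=entry.get("scale", "other"),
        )
        for entry in manifest["layers"]
    ]
    universe = manifest.get("universe")
    return MultiplexNetwork(layers, universe=universe)


def write_multiplex(m: MultiplexNetwork, outdir: str | Path, manifest_name: str = "manifest.json") -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for layer in m.layers:
        fname = f"{layer.name}.tsv"
        write_edge_list(layer, outdir / fname)
        entries.append({"name": layer.name, "scale": layer.scale, "path": fname})
    manifest = {"layers": entries, "universe": sorted(m.universe)}
    out = outdir / manifest_name
    out.write_text(json.dumps(manifest, indent=1))
    return out


def read_gene_sets(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file: set name, description, then members (duplicates collapsed)."""
    sets: dict[str, set[str]] = {}
    with Path(path).open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, description, members")
            sets[parts[0]] = set(parts[2:])
    logger.info("%s: read %d gene sets", path, len(sets))
    return sets


def write_gene_sets(sets: Mapping[str, set[str]], path: str | Path, descriptions: Mapping[str, str] | None = None) -> None:
    with Path(path).open("w") as fh:
        for name in sorted(sets):
            desc = (descriptions or {}).get(name, "")
            members = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")


def gene_sets_to_groups(sets: Mapping[str, set[str]]) -> list[DiseaseGroup]:
    return [
        DiseaseGroup(id=name, label=name, genes=frozenset(members))
        for name, members in sorted(sets.items())
    ]


def read_obo_lite(path: str | Path) -> Ontology:
    """Minimal OBO parser: [Term] stanzas with id:, name:, is_a: only.

    Obsolete stanzas are skipped; is_a references to unknown terms are an
    error listing the offenders.
    """
    parents: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    current: dict | None = None
    n_obsolete = 0

    def flush(stanza: dict | None) -> None:
        nonlocal n_obsolete
        if stanza is None or "id" not in stanza:
            return
        if stanza.get("obsolete"):
            n_obsolete += 1
            return
        parents[stanza["id"]] = set(stanza.get("is_a", []))
        names[stanza["id"]] = stanza.get("name", stanza["id"])

    with Path(path).open() as fh:
        in_term = False
        for raw in fh:
            line = raw.strip()
            if line == "[Term]":
                flush(current)
                current = {}
                in_term = True
            elif line.startswith("["):
                flush(current)
                current = None
                in_term = False
            elif in_term and current is not None:
                if line.startswith("id:"):
                    current["id"] = line[3:].strip()
                elif line.startswith("name:"):
                    current["name"] = line[5:].strip()
                elif line.startswith("is_a:"):
                    target = line[5:].strip().split("!")[0].strip()
                    current.setdefault("is_a", []).append(target)
                elif line.startswith("is_obsolete:") and line.split(":", 1)[1].strip() == "true":
                    current["obsolete"] = True
        flush(current)
    unknown = {
        t: sorted(ps - parents.keys()) for t, ps in parents.items() if ps - parents.keys()
    }
    if unknown:
        raise ValueError(f"is_a references to unknown terms: {unknown}")
    logger.info("%s: read %d terms, skipped %d obsolete", path, len(parents), n_obsolete)
    return Ontology(parents)


def write_obo_lite(o: Ontology, path: str | Path, names: Mapping[str, str] | None = None) -> None:
    with Path(path).open("w") as fh:
        fh.write("format-version: 1.2\n")
        for term in sorted(o.parents):
            fh.write(f"\n[Term]\nid: {term}\nname: {(names or {}).get(term, term)}\n")
            for p in sorted(o.parents[term]):
                fh.write(f"is_a: {p}\n")


def read_annotations(path: str | Path) -> AnnotationTable:
    """Two-column TSV (gene, term) -> AnnotationTable."""
    direct: dict[str, set[str]] = {}
    with Path(path).open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            direct.setdefault(parts[0], set()).add(parts[1])
    logger.info("%s: read annotations for %d genes", path, len(direct))
    return AnnotationTable(direct={g: frozenset(t) for g, t in direct.items()})


def write_annotations(a: AnnotationTable, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for g in sorted(a.direct):
            for t in sorted(a.direct[g]):
                fh.write(f"{g}\t{t}\n")


def read_expression(path: str | Path) -> ExpressionMatrix:
    """TSV with gene ids in the first column and sample ids in the header."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicated gene row(s): {dups}")
    return ExpressionMatrix(
        genes=[str(g) for g in df.index],
        samples=[str(s) for s in df.columns],
        values=df.to_numpy(dtype=float),
    )


def write_expression(x: ExpressionMatrix, path: str | Path) -> None:
    df = pd.DataFrame(x.values, index=x.genes, columns=x.samples)
    df.to_csv(path, sep="\t", float_format="%.10g", index_label="gene")


def read_patient_case(path: str | Path) -> PatientCase:
    data = json.loads(Path(path).read_text())
    return PatientCase(
        id=data["id"],
        phenotype_terms=frozenset(data["hpo_terms"]),
        candidates=frozenset(data["candidates"]),
        causal=data.get("causal"),
        disease_group=data["disease_group"],
    )


def write_patient_case(case: PatientCase, path: str | Path) -> None:
    data = {
        "id": case.id,
        "hpo_terms": sorted(case.phenotype_terms),
        "candidates": sorted(case.candidates),
        "causal": case.causal,
        "disease_group": case.disease_group,
    }
    Path(path).write_text(json.dumps(data, indent=1))
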