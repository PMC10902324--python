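"""Readers and writers for the plain-text interchange formats.

Layers are TSV edge lists (``gene_a TAB gene_b [TAB weight]``, ``#``
comments, optional one-column node file for isolated nodes); gene-set
catalogs are GMT; cohorts are TSV with semicolon-separated gene lists.
All writers emit lexicographically sorted records so outputs are
diff-stable.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set

from .core import GeneId, Layer, Partition, edge_key
from .persistence import CoMembership, Module, ResolutionGrid, SweepResult
from .stats import Cohort, GeneSetCatalog, Patient

logger = logging.getLogger("multicom")

_TRUE = {"1", "true", "yes", "y"}
_FALSE = {"0", "false", "no", "n"}


def _parse_bool(token: str, where: str) -> Optional[bool]:
    t = token.strip().lower()
    if t in ("", "na", "nan", "none"):
        return None
    if t in _TRUE:
        return True
    if t in _FALSE:
        return False
    raise ValueError(f"{where}: cannot parse boolean {token!r}")


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

def read_layer(path: str | Path, nodes_path: Optional[str | Path] = None,
               name: Optional[str] = None) -> Layer:
    """Read a TSV edge list; repeated undirected edges are deduplicated by
    summing weights (with a warning); self-loops are rejected."""
    path = Path(path)
    edges: Dict = {}
    nodes: Set[GeneId] = set()
    deduped = 0
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) not in (2, 3):
                raise ValueError(f"{path}:{lineno}: expected 2 or 3 tab-separated fields")
            a, b = fields[0].strip(), fields[1].strip()
            if not a or not b:
                raise ValueError(f"{path}:{lineno}: empty gene id")
            if a == b:
                raise ValueError(f"{path}:{lineno}: self-loop on {a!r}")
            if len(fields) == 3:
                try:
                    w = float(fields[2])
                except ValueError:
                    raise ValueError(f"{path}:{lineno}: bad weight {fields[2]!r}") from None
            else:
                w = 1.0
            if w <= 0:
                raise ValueError(f"{path}:{lineno}: non-positive weight {w}")
            k = edge_key(a, b)
            if k in edges:
                deduped += 1
            edges[k] = edges.get(k, 0.0) + w
    if deduped:
        logger.warning("%s: %d repeated undirected edges merged by summing weights", path, deduped)
    if nodes_path is not None:
        nodes = set(read_gene_list(nodes_path))
    return Layer(name=name or path.stem, nodes=nodes, edges=edges)


def write_layer(layer: Layer, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for (a, b) in sorted(layer.edges):
            w = layer.edges[(a, b)]
            if w == 1.0:
                fh.write(f"{a}\t{b}\n")
            else:
                fh.write(f"{a}\t{b}\t{w:g}\n")


# ---------------------------------------------------------------------------
# Gene lists and GMT catalogs
# ---------------------------------------------------------------------------

def read_gene_list(path: str | Path) -> List[GeneId]:
    out: List[GeneId] = []
    with Path(path).open() as fh:
        for raw in fh:
            t = raw.strip()
            if t and not t.startswith("#"):
                out.append(t)
    return out


def write_gene_list(genes: Iterable[GeneId], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for g in sorted(set(genes)):
            fh.write(f"{g}\n")


def read_gmt(path: str | Path) -> GeneSetCatalog:
    """Read a GMT file (set name TAB description TAB genes...)."""
    path = Path(path)
    sets: Dict[str, Set[GeneId]] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
            name = fields[0].strip()
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            genes = [g.strip() for g in fields[2:] if g.strip()]
            uniq = set(genes)
            if len(uniq) < len(genes):
                logger.warning("%s:%d: duplicate genes within set %r deduplicated",
                               path, lineno, name)
            if not uniq:
                raise ValueError(f"{path}:{lineno}: set {name!r} has no genes")
            sets[name] = uniq
    return GeneSetCatalog(sets)


def write_gmt(catalog: GeneSetCatalog, path: str | Path, description: str = "na") -> None:
    with Path(path).open("w") as fh:
        for name in sorted(catalog.sets):
            genes = "\t".join(sorted(catalog.sets[name]))
            fh.write(f"{name}\t{description}\t{genes}\n")


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

COHORT_COLUMNS = ("patient_id", "severity", "fine_label", "treatment", "compound_het", "cnv")


def _parse_genes(token: str) -> Set[GeneId]:
    return {g.strip() for g in token.split(";") if g.strip()}


def read_cohort(path: str | Path) -> Cohort:
    """Read a cohort TSV.  Header columns: patient_id, severity,
    fine_label, treatment, compound_het, cnv, then any number of binary
    clinical variables.  Gene lists are semicolon-separated."""
    path = Path(path)
    patients: List[Patient] = []
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header[:6]) != COHORT_COLUMNS:
            raise ValueError(
                f"{path}: expected header starting with {COHORT_COLUMNS}, got {header[:6]}"
            )
        clinical_cols = header[6:]
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != len(header):
                raise ValueError(f"{path}:{lineno}: expected {len(header)} fields")
            pid, severity, fine, treat, chet, cnv = fields[:6]
            if severity not in ("severe", "not_severe"):
                raise ValueError(
                    f"{path}:{lineno}: unknown severity {severity!r} "
                    "(accepted: severe, not_severe)"
                )
            patients.append(
                Patient(
                    id=pid.strip(),
                    severity=severity,
                    fine_label=fine.strip() or None,
                    treatment=_parse_bool(treat, f"{path}:{lineno}"),
                    compound_het_genes=_parse_genes(chet),
                    cnv_genes=_parse_genes(cnv),
                    clinical_vars={
                        c: _parse_bool(v, f"{path}:{lineno}")
                        for c, v in zip(clinical_cols, fields[6:])
                    },
                )
            )
    return Cohort(patients)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    clinical_cols = sorted({c for p in cohort.patients for c in p.clinical_vars})

    def fmt_bool(v: Optional[bool]) -> str:
        return "" if v is None else ("1" if v else "0")

    with Path(path).open("w") as fh:
        fh.write("\t".join(COHORT_COLUMNS + tuple(clinical_cols)) + "\n")
        for p in sorted(cohort.patients, key=lambda q: q.id):
            row = [
                p.id,
                p.severity,
                p.fine_label or "",
                fmt_bool(p.treatment),
                ";".join(sorted(p.compound_het_genes)),
                ";".join(sorted(p.cnv_genes)),
            ] + [fmt_bool(p.clinical_vars.get(c)) for c in clinical_cols]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Partitions and sweep archives
# ---------------------------------------------------------------------------

def write_partition(partition: Partition, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for g in sorted(partition.assignment):
            fh.write(f"{g}\t{partition.assignment[g]}\n")


def read_partition(path: str | Path) -> Partition:
    path = Path(path)
    asg: Dict[GeneId, int] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 fields")
            if fields[0] in asg:
                raise ValueError(f"{path}:{lineno}: duplicate gene {fields[0]!r}")
            asg[fields[0]] = int(fields[1])
    return Partition(asg)


def write_sweep_archive(sweep_result: SweepResult, outdir: str | Path) -> None:
    """Directory of per-gamma partition TSVs plus a manifest JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = []
    for i, (gamma, p) in enumerate(zip(sweep_result.grid.values, sweep_result.partitions)):
        fname = f"partition_{i:02d}_gamma_{gamma:g}.tsv"
        write_partition(p, outdir / fname)
        files.append(fname)
    manifest = {
        "grid": list(sweep_result.grid.values),
        "grid_note": "evenly spaced sample of the resolution interval",
        "seeds": sweep_result.seeds,
        "q_values": sweep_result.q_values,
        "n_communities": [p.n_communities for p in sweep_result.partitions],
        "partition_files": files,
    }
    write_json(manifest, outdir / "manifest.json")


def read_sweep_archive(indir: str | Path) -> SweepResult:
    indir = Path(indir)
    with (indir / "manifest.json").open() as fh:
        manifest = json.load(fh)
    partitions = [read_partition(indir / f) for f in manifest["partition_files"]]
    return SweepResult(
        grid=ResolutionGrid(tuple(manifest["grid"])),
        partitions=partitions,
        seeds=list(manifest["seeds"]),
        q_values=list(manifest["q_values"]),
    )


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def write_json(obj, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def module_report_dict(modules_by_n: Mapping[int, Sequence[Module]],
                       core_sizes: Optional[Mapping[int, int]] = None) -> dict:
    return {
        "modules_by_threshold": {
            str(n): [
                {"genes": sorted(m.genes), "size": m.size, "anchored": m.anchored}
                for m in mods
            ]
            for n, mods in modules_by_n.items()
        },
        "persistent_core_sizes": {str(k): v for k, v in (core_sizes or {}).items()},
    }


def write_module_report(modules_by_n: Mapping[int, Sequence[Module]], path: str | Path,
                        core_sizes: Optional[Mapping[int, int]] = None) -> None:
    write_json(module_report_dict(modules_by_n, core_sizes), path)


def write_comembership_edges(comember: CoMembership, path: str | Path,
                             min_count: int = 1) -> None:
    """Edge list of the co-membership graph for external visualization."""
    with Path(path).open("w") as fh:
        fh.write("gene_a\tgene_b\tcount\n")
        for (a, b) in sorted(comember.counts):
            c = comember.counts[(a, b)]
            if c >= min_count:
                fh.write(f"{a}\t{b}\t{c}\n")
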