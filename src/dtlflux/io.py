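"""Readers and writers for the pipeline's file formats.

All tabular outputs are TSV with one header line, optionally preceded
by ``#``-prefixed metadata lines, so every artefact is diff-friendly
and language-neutral.  Trees are Newick with labelled internal nodes,
proteomes FASTA, annotations a GFF3 subset (type CDS), configuration a
YAML key-value file.  Coordinates are 0-based half-open internally and
1-based inclusive in GFF, matching the convention at the interface
only.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Mapping, Optional, Union

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .matrix import PresenceMatrix
from .simulate import Event, EventLog, GeneRecord, SyntheticAnnotation
from .tree import SpeciesTree

__all__ = [
    "read_newick", "write_newick",
    "read_presence_matrix", "write_presence_matrix",
    "read_event_log", "write_event_log",
    "write_tally", "write_tsv",
    "read_fasta_proteomes", "write_fasta_proteomes",
    "read_gff", "write_gff",
    "read_config", "write_config",
    "file_sha256",
]

PathLike = Union[str, Path]


# -- trees ------------------------------------------------------------------

def read_newick(path: PathLike, default_length: float = 1.0,
                resolve_multifurcations: bool = False) -> SpeciesTree:
    """Read a rooted Newick tree.

    Unlabelled internal nodes get deterministic ids ("n" + preorder
    index); missing branch lengths default to 1.0 with a warning.
    Multifurcations raise unless ``resolve_multifurcations`` is set.
    """
    text = Path(path).read_text()
    return SpeciesTree.from_newick(
        text, default_length=default_length,
        resolve_multifurcations=resolve_multifurcations,
    )


def write_newick(tree: SpeciesTree, path: PathLike) -> None:
    Path(path).write_text(tree.to_newick())


# -- presence matrix --------------------------------------------------------

def read_presence_matrix(path: PathLike) -> PresenceMatrix:
    """Read a families x genomes TSV (header = genome ids).

    Cells must be nonnegative integers (counts > 1 are preserved; the
    binarised view is derived on demand).  Ragged rows, duplicate
    family ids and non-numeric cells raise with the offending line
    number.
    """
    path = Path(path)
    rows: list[list[int]] = []
    families: list[str] = []
    header: Optional[list[str]] = None
    seen: dict[str, int] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields[1:]
                continue
            if len(fields) != len(header) + 1:
                raise ValueError(
                    f"{path.name}:{lineno}: expected {len(header) + 1} "
                    f"columns, found {len(fields)}")
            fam = fields[0]
            if fam in seen:
                raise ValueError(
                    f"{path.name}:{lineno}: duplicate family id {fam!r} "
                    f"(first seen at line {seen[fam]})")
            seen[fam] = lineno
            try:
                values = [int(v) for v in fields[1:]]
            except ValueError:
                raise ValueError(
                    f"{path.name}:{lineno}: non-numeric cell in row {fam!r}"
                ) from None
            if any(v < 0 for v in values):
                raise ValueError(
                    f"{path.name}:{lineno}: negative count in row {fam!r}")
            families.append(fam)
            rows.append(values)
    if header is None:
        raise ValueError(f"{path.name}: empty matrix file")
    frame = pd.DataFrame(rows, index=families, columns=header)
    return PresenceMatrix(frame)


def write_presence_matrix(matrix: PresenceMatrix, path: PathLike,
                          metadata: Optional[Mapping[str, str]] = None) -> None:
    with Path(path).open("w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}={value}\n")
        fh.write("family\t" + "\t".join(matrix.genomes) + "\n")
        for fam, row in matrix.counts.iterrows():
            fh.write(fam + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


# -- event logs and tallies -------------------------------------------------

def write_event_log(log: EventLog, path: PathLike) -> None:
    with Path(path).open("w") as fh:
        fh.write("# root_presence=" +
                 ",".join(f"{f}:{k}" for f, k in sorted(log.root_presence.items()))
                 + "\n")
        fh.write("family\tbranch\ttype\tdonor\ttime\n")
        for e in log.events:
            fh.write(f"{e.family}\t{e.branch}\t{e.type}\t{e.donor or ''}\t"
                     f"{e.time:.10g}\n")


def read_event_log(path: PathLike) -> EventLog:
    path = Path(path)
    root_presence: dict[str, int] = {}
    events: list[Event] = []
    with path.open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# root_presence="):
                payload = line.split("=", 1)[1]
                if payload:
                    for item in payload.split(","):
                        fam, k = item.split(":")
                        root_presence[fam] = int(k)
                continue
            if not line or line.startswith("#") or line.startswith("family\t"):
                continue
            fam, branch, etype, donor, time = line.split("\t")
            events.append(Event(fam, branch, etype, donor or None, float(time)))
    return EventLog(events, root_presence)


def write_tally(tally, path: PathLike,
                metadata: Optional[Mapping[str, str]] = None) -> None:
    """Write a BranchEventTally as node x D/T/L/O TSV."""
    frame = tally.counts.copy()
    frame.insert(0, "node", frame.index)
    write_tsv(frame, path, metadata=metadata, index=False)


def write_tsv(frame: pd.DataFrame, path: PathLike,
              metadata: Optional[Mapping[str, str]] = None,
              index: bool = False) -> None:
    with Path(path).open("w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}={value}\n")
        frame.to_csv(fh, sep="\t", index=index)


# -- FASTA proteomes --------------------------------------------------------

def write_fasta_proteomes(sequences: Mapping[str, list[str]],
                          path: PathLike) -> None:
    """One FASTA with records ``{genome}|{i}`` per protein."""
    records = [
        SeqRecord(Seq(seq), id=f"{genome}|{i + 1}", description="")
        for genome, seqs in sequences.items()
        for i, seq in enumerate(seqs)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta_proteomes(path: PathLike) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        genome = rec.id.rsplit("|", 1)[0]
        out.setdefault(genome, []).append(str(rec.seq))
    return out


# -- GFF3 subset ------------------------------------------------------------

def write_gff(annotation: SyntheticAnnotation, path: PathLike) -> None:
    """Write the CDS records of one genome as a GFF3 subset.

    Internal 0-based half-open coordinates become 1-based inclusive.
    Genome metadata (length, GC) is carried in directives.
    """
    with Path(path).open("w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {annotation.contig} 1 {annotation.length}\n")
        fh.write(f"#!genome-id {annotation.genome_id}\n")
        fh.write(f"#!gc {annotation.gc:.6g}\n")
        for i, g in enumerate(annotation.genes, start=1):
            fh.write("\t".join([
                g.contig, "dtlflux", "CDS", str(g.start + 1), str(g.end),
                ".", g.strand, ".", f"ID=cds{i}",
            ]) + "\n")


def read_gff(path: PathLike) -> SyntheticAnnotation:
    path = Path(path)
    genome_id, contig, length, gc = path.stem, None, None, 0.5
    genes: list[GeneRecord] = []
    with path.open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##sequence-region"):
                _, contig, _start, end = line.split()
                length = int(end)
            elif line.startswith("#!genome-id"):
                genome_id = line.split(None, 1)[1]
            elif line.startswith("#!gc"):
                gc = float(line.split(None, 1)[1])
            elif line.startswith("#") or not line:
                continue
            else:
                fields = line.split("\t")
                if len(fields) != 9 or fields[2] != "CDS":
                    continue
                seqid, _src, _type, start, end, _score, strand, _phase, _attr = fields
                genes.append(GeneRecord(seqid, int(start) - 1, int(end), strand))
                contig = contig or seqid
    if length is None:
        length = max((g.end for g in genes), default=0)
    return SyntheticAnnotation(genome_id, contig or "contig1", length, gc, genes)


# -- configuration ----------------------------------------------------------

def read_config(path: PathLike) -> dict:
    with Path(path).open() as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config must be a key-value mapping")
    return data


def write_config(config: Mapping, path: PathLike) -> None:
    with Path(path).open("w") as fh:
        yaml.safe_dump(dict(config), fh, sort_keys=True)


def file_sha256(path: PathLike) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
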