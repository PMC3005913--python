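"""File formats: FASTA, structure strings, alignments, dictionaries, outputs.

All on-disk coordinates are 1-based inclusive; parsing converts to the
internal 0-based convention exactly once. Three alignment dialects are
accepted: BLAST XML, BLAST tabular with aligned-sequence columns, and a
``simple-tsv`` dialect used by the synthetic-homolog generator so that no
search binaries are ever required.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SearchIO, SeqIO

from .dictionary import SynonymDictionary, WordRecord
from .evaluation import AccuracyTable
from .predictor import Prediction
from .types import LocalAlignment, ProteinChain

DICT_FORMAT_VERSION = "1"

# --------------------------------------------------------------------------
# sequences and structure strings


def read_fasta(path: str | Path) -> list[ProteinChain]:
    """Read a FASTA file into chains (no structure), order preserved."""
    chains = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not rec.id:
            raise ValueError(f"{path}: record with empty header")
        if not seq:
            raise ValueError(f"{path}: record {rec.id!r} has an empty sequence")
        chains.append(ProteinChain(rec.id, seq))
    return chains


def write_fasta(chains: Sequence[ProteinChain], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in chains:
            fh.write(f">{c.id}\n{c.sequence}\n")


def read_ss3(path: str | Path) -> dict[str, str]:
    """Read a FASTA-like file of per-residue H/E/C strings keyed by id."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        ss = str(rec.seq).upper()
        bad = set(ss) - set("HEC")
        if bad:
            raise ValueError(
                f"{path}: record {rec.id!r} has non-HEC states {sorted(bad)}"
            )
        out[rec.id] = ss
    return out


def write_ss3(ss_by_id: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for cid, ss in ss_by_id.items():
            fh.write(f">{cid}\n{ss}\n")


def attach_ss3(
    chains: Sequence[ProteinChain], ss_by_id: Mapping[str, str]
) -> list[ProteinChain]:
    """Pair chains with their structure strings (lengths must agree)."""
    out = []
    for c in chains:
        if c.id not in ss_by_id:
            raise KeyError(f"no structure string for chain {c.id!r}")
        out.append(ProteinChain(c.id, c.sequence, ss_by_id[c.id]))
    return out


_DSSP_TO_3 = {
    "H": "H", "G": "H", "I": "H",   # alpha / 3-10 / pi helices
    "E": "E", "B": "E",             # strand / isolated beta bridge
    "T": "C", "S": "C", " ": "C", "-": "C", "C": "C",
}


def reduce_dssp_states(ss8: str) -> str:
    """Reduce an 8-state DSSP string to three states.

    Convention: H, G, I -> H; E, B -> E; everything else (T, S, blank,
    '-') -> C. Length is preserved. Raises on codes outside the DSSP
    alphabet, reporting the character and its 1-based position.
    """
    out = []
    for i, c in enumerate(ss8):
        try:
            out.append(_DSSP_TO_3[c])
        except KeyError:
            raise ValueError(
                f"unknown DSSP code {c!r} at position {i + 1}"
            ) from None
    return "".join(out)


# --------------------------------------------------------------------------
# alignments

ALIGNMENT_DIALECTS = ("simple-tsv", "tabular-with-sequences", "xml")

#: column order of the tabular dialect (BLAST
#: ``-outfmt "6 qseqid sseqid qstart sstart evalue qseq sseq"``)
TABULAR_COLUMNS = ("qseqid", "sseqid", "qstart", "sstart", "evalue", "qseq", "sseq")


def parse_blast_alignments(
    path: str | Path,
    dialect: str = "simple-tsv",
    evalue_threshold: float | None = 1e-3,
) -> list[LocalAlignment]:
    """Parse local alignments (one per HSP), dropping weak hits.

    ``evalue_threshold`` drops HSPs with e-value strictly above it
    (0.001 mirrors the customary safe-homology search cut); pass None to
    keep everything.
    """
    if dialect not in ALIGNMENT_DIALECTS:
        raise ValueError(
            f"unusable dialect {dialect!r}; expected one of {ALIGNMENT_DIALECTS}"
        )
    if dialect == "xml":
        alns = _parse_xml(path)
    else:
        alns = _parse_tsv(path, dialect)
    if evalue_threshold is not None:
        alns = [a for a in alns if a.evalue <= evalue_threshold]
    return alns


def _parse_xml(path: str | Path) -> list[LocalAlignment]:
    out = []
    for qresult in SearchIO.parse(str(path), "blast-xml"):
        for hit in qresult:
            for hsp in hit.hsps:
                out.append(
                    LocalAlignment(
                        query_id=qresult.id,
                        subject_id=hit.id,
                        query_start=hsp.query_start + 1,  # SearchIO is 0-based
                        subject_start=hsp.hit_start + 1,
                        query_aln=str(hsp.query.seq).upper(),
                        subject_aln=str(hsp.hit.seq).upper(),
                        evalue=float(hsp.evalue),
                    )
                )
    return out


def _parse_tsv(path: str | Path, dialect: str) -> list[LocalAlignment]:
    out = []
    ncols = 7
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != ncols:
                raise ValueError(
                    f"{path}:{lineno}: expected {ncols} columns, got {len(parts)}"
                    + (
                        "; the tabular dialect requires qseq/sseq columns"
                        if dialect == "tabular-with-sequences"
                        else ""
                    )
                )
            if dialect == "simple-tsv":
                qid, sid, qstart, sstart, qaln, saln, ev = parts
            else:  # tabular-with-sequences
                qid, sid, qstart, sstart, ev, qaln, saln = parts
            if len(qaln) != len(saln):
                raise ValueError(
                    f"{path}:{lineno}: aligned rows have different lengths"
                )
            try:
                out.append(
                    LocalAlignment(
                        query_id=qid,
                        subject_id=sid,
                        query_start=int(qstart),
                        subject_start=int(sstart),
                        query_aln=qaln.upper(),
                        subject_aln=saln.upper(),
                        evalue=float(ev),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return out


def write_alignments(
    alignments: Iterable[LocalAlignment], path: str | Path
) -> None:
    """Write alignments in the simple-tsv dialect."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(
            ("query_id", "subject_id", "query_start", "subject_start",
             "query_aln", "subject_aln", "evalue")
        ) + "\n")
        for a in alignments:
            fh.write(
                f"{a.query_id}\t{a.subject_id}\t{a.query_start}\t"
                f"{a.subject_start}\t{a.query_aln}\t{a.subject_aln}\t"
                f"{a.evalue:g}\n"
            )


# --------------------------------------------------------------------------
# dictionary serialization


def write_dictionary(dictionary: SynonymDictionary, path: str | Path) -> None:
    """Serialize a dictionary: '#'-prefixed header block, then one TSV row
    per (word, source, structure) record."""
    with open(path, "w") as fh:
        fh.write(f"#synpss-dict\tv{DICT_FORMAT_VERSION}\n")
        fh.write(f"#n\t{dictionary.n}\n")
        fh.write(f"#provenance\t{json.dumps(dictionary.provenance, sort_keys=True)}\n")
        fh.write("#word\tsource_id\tss\tsimilarity_level\tfrequency\tpositions\n")
        for word in sorted(dictionary.words()):
            for rec in sorted(
                dictionary.records(word), key=lambda r: (r.source_id, r.ss)
            ):
                pos = ",".join(map(str, rec.source_positions)) or "-"
                fh.write(
                    f"{word}\t{rec.source_id}\t{rec.ss}\t"
                    f"{rec.similarity_level}\t{rec.frequency}\t{pos}\n"
                )


def read_dictionary(path: str | Path) -> SynonymDictionary:
    entries: dict[str, list[WordRecord]] = {}
    n = None
    provenance: dict = {}
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if not first.startswith("#synpss-dict"):
            raise ValueError(f"{path}: not a dictionary file")
        version = first.split("\t")[1].lstrip("v") if "\t" in first else ""
        if version != DICT_FORMAT_VERSION:
            raise ValueError(
                f"{path}: unsupported dictionary format version {version!r}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split("\t", 1)
                if parts[0] == "n":
                    n = int(parts[1])
                elif parts[0] == "provenance":
                    provenance = json.loads(parts[1])
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise ValueError(
                    f"{path}:{lineno}: truncated record ({len(fields)} fields)"
                )
            word, src, ss, lvl, freq, pos = fields
            positions = (
                () if pos == "-" else tuple(int(p) for p in pos.split(","))
            )
            entries.setdefault(word, []).append(
                WordRecord(word, src, ss, int(lvl), int(freq), positions)
            )
    if n is None:
        raise ValueError(f"{path}: missing word-length header")
    return SynonymDictionary(n, entries, provenance)


# --------------------------------------------------------------------------
# predictions and calibration tables


def write_prediction(
    prediction: Prediction, path: str | Path, sequence: str | None = None
) -> None:
    """Write a per-residue TSV (index, residue, state, confidence).

    The predicted structure is also embedded as a FASTA-like header comment
    so the file is self-contained.
    """
    seq = sequence or "?" * len(prediction.ss3)
    with open(path, "w") as fh:
        fh.write(f"#>{prediction.target_id}\n")
        fh.write(f"#{prediction.ss3}\n")
        fh.write("#index\tresidue\tstate\tconfidence\n")
        for i, (aa, state, conf) in enumerate(
            zip(seq, prediction.ss3, prediction.confidence), start=1
        ):
            fh.write(f"{i}\t{aa}\t{state}\t{int(conf)}\n")


def read_prediction(path: str | Path) -> Prediction:
    target_id = "unknown"
    states: list[str] = []
    confs: list[int] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#>"):
                target_id = line[2:]
                continue
            if line.startswith("#") or not line:
                continue
            _, _, state, conf = line.split("\t")
            states.append(state)
            confs.append(int(conf))
    return Prediction(target_id, "".join(states), np.array(confs, dtype=int))


def write_accuracy_table(table: AccuracyTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#method\t{table.method_id}\n")
        fh.write("#level\tmean_q3\tcount\n")
        for lvl in range(10):
            acc, count = table.rows.get(lvl, (float("nan"), 0))
            fh.write(f"{lvl}\t{acc:.4f}\t{count}\n")


def read_accuracy_table(path: str | Path) -> AccuracyTable:
    method = "method"
    rows: dict[int, tuple[float, int]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#method"):
                method = line.split("\t")[1]
                continue
            if line.startswith("#") or not line:
                continue
            lvl, acc, count = line.split("\t")
            rows[int(lvl)] = (float(acc), int(count))
    return AccuracyTable(method, rows)
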