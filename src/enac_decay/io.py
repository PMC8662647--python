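"""Readers and writers for the plain-text formats the package consumes.

FASTA via Biopython; GFF3 for anchors and lesions (1-based inclusive on
disk, 0-based half-open in memory); exon reference models as a FASTA of
exon sequences plus a TSV sidecar of (label, phase); TEVC traces as a
two-column CSV with an epoch sidecar CSV; integrity reports as JSON.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .ephys import Epoch, TevcTrace
from .integrity import (
    Anchor,
    ExonReference,
    IntegrityReport,
    Lesion,
    ReferenceExon,
)


# ---------------------------------------------------------------------------
# sequences and annotations
# ---------------------------------------------------------------------------

def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(path: str, sequences: dict[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, path, "fasta")


def read_gff3_anchors(path: str) -> dict[str, list[Anchor]]:
    """Anchor gene annotations per sequence id, from a minimal GFF3."""
    out: dict[str, list[Anchor]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                continue
            seqid, _, _, start, end, _, strand, _, attrs = fields[:9]
            name = None
            for item in attrs.split(";"):
                key, _, value = item.partition("=")
                if key.strip() in ("Name", "gene", "ID"):
                    name = value.strip()
                    break
            if name is None:
                continue
            out.setdefault(seqid, []).append(
                Anchor(name=name, start=int(start) - 1, end=int(end),
                       strand=strand if strand in "+-" else "+")
            )
    return out


def write_lesions_gff3(path: str, lesions: Iterable[Lesion],
                       seqid: str = "locus") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for n, lesion in enumerate(lesions, start=1):
            start = 1 if lesion.start is None else lesion.start + 1
            end = 1 if lesion.end is None else lesion.end
            fh.write(
                f"{seqid}\tenac-decay\t{lesion.kind}\t{start}\t{end}\t.\t+\t.\t"
                f"ID=lesion{n};exon={lesion.exon};note={lesion.detail}\n"
            )


def load_exon_reference(fasta_path: str, sidecar_path: str) -> ExonReference:
    """Reference gene model from a FASTA of exons plus a (label, phase) TSV."""
    seqs = read_fasta(fasta_path)
    sidecar = pd.read_csv(sidecar_path, sep="\t", dtype={"label": str})
    exons = [
        ReferenceExon(label=row.label, sequence=seqs[row.label],
                      phase=int(row.phase))
        for row in sidecar.itertuples()
    ]
    return ExonReference(exons)


def save_exon_reference(reference: ExonReference, fasta_path: str,
                        sidecar_path: str) -> None:
    write_fasta(fasta_path, {e.label: e.sequence for e in reference.exons})
    pd.DataFrame(
        {"label": [e.label for e in reference.exons],
         "phase": [e.phase for e in reference.exons]}
    ).to_csv(sidecar_path, sep="\t", index=False)


def report_to_json(report: IntegrityReport, path: str | None = None) -> str:
    payload = dataclasses.asdict(report)
    text = json.dumps(payload, indent=2, default=str)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------

def read_trace_csv(trace_path: str, epochs_path: str) -> TevcTrace:
    """Trace CSV (time_s, current_uA) + epoch CSV (start_s, end_s, na_mM,
    drug, conc)."""
    tr = pd.read_csv(trace_path)
    ep = pd.read_csv(epochs_path)
    epochs = [
        Epoch(start=row.start_s, end=row.end_s, na_mM=row.na_mM,
              drug=str(row.drug), conc=float(row.conc))
        for row in ep.itertuples()
    ]
    return TevcTrace(
        time=tr["time_s"].to_numpy(dtype=float),
        current=tr["current_uA"].to_numpy(dtype=float),
        epochs=epochs,
    )


def write_trace_csv(trace: TevcTrace, trace_path: str, epochs_path: str) -> None:
    pd.DataFrame({"time_s": trace.time, "current_uA": trace.current}).to_csv(
        trace_path, index=False
    )
    pd.DataFrame(
        [
            {"start_s": e.start, "end_s": e.end, "na_mM": e.na_mM,
             "drug": e.drug, "conc": e.conc}
            for e in trace.epochs
        ]
    ).to_csv(epochs_path, index=False)


# ---------------------------------------------------------------------------
# occurrences
# ---------------------------------------------------------------------------

def read_occurrences_tsv(path: str) -> pd.DataFrame:
    """Darwin-Core-like TSV: species, decimalLatitude, decimalLongitude, year."""
    return pd.read_csv(path, sep="\t")


def write_occurrences_tsv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)
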