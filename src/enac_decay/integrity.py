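"""Synteny-anchored integrity screening of SCNN1D-like loci.

The delta-ENaC gene (*SCNN1D*) sits between the conserved neighbours
*UBE2J2* and *ACAP3* in rodent genomes.  Screening a genome for a
functional copy therefore reduces to: cut out the inter-anchor segment,
map each exon of a 12-exon reference gene model onto it by local
alignment, and inspect the mapped exons for open-reading-frame lesions
(frameshifts, premature stop codons, splice-site disruptions, missing
exons).  A locus with no lesion is ``intact``; with at least one lesion it
is a ``pseudogene``; when almost nothing maps the gene is ``absent``.

A special case is the Hystricognathi "super-exon": exons 11 and 12 fused
by loss of the intervening splice sites, with the short intron retained
in frame.  Such a fusion is a feature, not a defect, and is checked
before splice lesions are called.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from Bio.Align import PairwiseAligner
from Bio.Seq import Seq

from .errors import (
    AnchorNotFound,
    ChainingError,
    InvalidAnchors,
    NomenclatureError,
)

CANONICAL_DONOR = "GT"
CANONICAL_ACCEPTOR = "AG"
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

LESION_KINDS = (
    "frameshift",
    "premature_stop",
    "splice_donor_loss",
    "splice_acceptor_loss",
    "exon_missing",
)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Anchor:
    """A flanking-gene annotation on the source sequence (0-based half-open)."""

    name: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise InvalidAnchors(f"anchor {self.name}: end <= start")
        if self.strand not in "+-":
            raise InvalidAnchors(f"anchor {self.name}: bad strand {self.strand!r}")


@dataclass
class LocusRecord:
    """An anchored genomic segment in gene-forward orientation."""

    species: str
    assembly: str
    sequence: str
    strand: str
    region_start: int
    region_end: int
    anchors: tuple[Anchor, Anchor]

    def __post_init__(self) -> None:
        if self.region_end <= self.region_start:
            raise ValueError("region_end must exceed region_start")
        if len(self.sequence) != self.region_end - self.region_start:
            raise ValueError("sequence length must equal region span")
        for a in self.anchors:
            if a.start < self.region_end and a.end > self.region_start:
                raise InvalidAnchors(f"anchor {a.name} overlaps the locus region")


@dataclass(frozen=True)
class ReferenceExon:
    label: str
    sequence: str
    phase: int = 0


class ExonReference:
    """An ordered exon model of the gene (labels ``1a/1b/1``, ``2`` .. ``13``).

    Exon 2 carries the first transmembrane segment (TM1) and exon 13 the
    second (TM2); phases record the reading-frame offset at each exon start.
    """

    def __init__(
        self,
        exons: Sequence[ReferenceExon],
        tm1_label: str = "2",
        tm2_label: str = "13",
    ) -> None:
        if not exons:
            raise ValueError("reference needs at least one exon")
        self.exons = list(exons)
        self.tm1_label = tm1_label
        self.tm2_label = tm2_label
        labels = [e.label for e in self.exons]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate exon labels")

    @property
    def labels(self) -> list[str]:
        return [e.label for e in self.exons]

    def __getitem__(self, label: str) -> ReferenceExon:
        for e in self.exons:
            if e.label == label:
                return e
        raise KeyError(label)

    @property
    def cds(self) -> str:
        return "".join(e.sequence for e in self.exons)


@dataclass
class ExonHit:
    """Best local placement of one reference exon on the locus."""

    label: str
    start: int                 # extended locus coords, 0-based half-open
    end: int
    identity: float            # percent, over aligned columns
    insertions: int            # locus bases absent from the reference exon
    deletions: int             # reference bases absent from the locus
    donor: str                 # dinucleotide after `end`
    acceptor: str              # dinucleotide before `start`
    score: float
    indels: list[tuple[str, int, int]] = field(default_factory=list)
    # indels: (kind 'ins'|'del', position within segment, length)

    @property
    def net_shift(self) -> int:
        return self.insertions - self.deletions

    def segment(self, locus: LocusRecord) -> str:
        return locus.sequence[self.start:self.end]


@dataclass(frozen=True)
class Lesion:
    kind: str
    start: Optional[int]       # locus coords, None for exon_missing
    end: Optional[int]
    exon: str
    detail: str = ""

    def __post_init__(self) -> None:
        if self.kind not in LESION_KINDS:
            raise ValueError(f"unknown lesion kind {self.kind!r}")


@dataclass(frozen=True)
class FusionRecord:
    labels: tuple[str, str]
    retained_length: int       # nt of intron retained in the transcript
    inserted_residues: int     # retained_length / 3
    start: int                 # locus coords of the retained intron
    end: int


@dataclass
class IntegrityReport:
    status: str                # intact | pseudogene | absent
    lesions: list[Lesion]
    fusion: Optional[FusionRecord]
    cds: str
    protein: str
    unresolved_exons: list[str] = field(default_factory=list)
    hits: list[ExonHit] = field(default_factory=list)


# ---------------------------------------------------------------------------
# region extraction
# ---------------------------------------------------------------------------

def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def extract_target_region(
    genome: str,
    anchors: Iterable[Anchor],
    *,
    upstream_gene: str = "UBE2J2",
    downstream_gene: str = "ACAP3",
    species: str = "",
    assembly: str = "",
) -> LocusRecord:
    """Cut the inter-anchor segment and orient it gene-forward.

    The two anchors must be annotated on the same strand.  On the minus
    strand the segment is reverse-complemented so that the putative gene
    always reads left to right with *UBE2J2* upstream.
    """
    by_name = {a.name.upper(): a for a in anchors}
    try:
        up = by_name[upstream_gene.upper()]
        down = by_name[downstream_gene.upper()]
    except KeyError as missing:
        raise AnchorNotFound(f"anchor {missing.args[0]} not annotated") from None
    if up.strand != down.strand:
        raise InvalidAnchors("anchors lie on different strands")
    left, right = (up, down) if up.start <= down.start else (down, up)
    if left.end > right.start:
        raise InvalidAnchors("anchor annotations overlap")
    seg = genome[left.end:right.start]
    if not seg:
        raise InvalidAnchors("no sequence between anchors")
    strand = up.strand
    if strand == "-":
        seg = _revcomp(seg)
    return LocusRecord(
        species=species,
        assembly=assembly,
        sequence=seg,
        strand=strand,
        region_start=left.end,
        region_end=right.start,
        anchors=(up, down),
    )


# ---------------------------------------------------------------------------
# exon mapping
# ---------------------------------------------------------------------------

def _make_aligner(match: float, mismatch: float, open_gap: float,
                  extend_gap: float) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    return aligner


def _align_exon(aligner: PairwiseAligner, locus_seq: str, exon: ReferenceExon):
    """Best local alignment of one exon; returns a raw hit dict or None."""
    alns = aligner.align(locus_seq, exon.sequence)
    if len(alns) == 0 or alns.score <= 0:
        return None
    aln = alns[0]
    tblocks, qblocks = aln.aligned
    if len(tblocks) == 0:
        return None
    matches = 0
    columns = 0
    insertions = deletions = 0
    indels: list[tuple[str, int, int]] = []
    t0 = tblocks[0][0]
    for (ts, te), (qs, qe) in zip(tblocks, qblocks):
        for i in range(te - ts):
            columns += 1
            if locus_seq[ts + i] == exon.sequence[qs + i]:
                matches += 1
    for k in range(1, len(tblocks)):
        tgap = tblocks[k][0] - tblocks[k - 1][1]
        qgap = qblocks[k][0] - qblocks[k - 1][1]
        if tgap:
            insertions += tgap
            indels.append(("ins", tblocks[k - 1][1] - t0, tgap))
            columns += tgap
        if qgap:
            deletions += qgap
            indels.append(("del", tblocks[k - 1][1] - t0, qgap))
            columns += qgap
    q_start, q_end = qblocks[0][0], qblocks[-1][1]
    t_start, t_end = tblocks[0][0], tblocks[-1][1]
    # extend clipped exon termini 1:1 onto the locus
    ext_left = min(q_start, t_start)
    ext_right = min(len(exon.sequence) - q_end, len(locus_seq) - t_end)
    return {
        "label": exon.label,
        "start": t_start - ext_left,
        "end": t_end + ext_right,
        "identity": 100.0 * matches / columns if columns else 0.0,
        "coverage": 100.0 * (q_end - q_start) / len(exon.sequence),
        "insertions": insertions,
        "deletions": deletions,
        "indels": [(k, p + ext_left, l) for (k, p, l) in indels],
        "score": float(alns.score),
    }


def _chain_hits(raw_hits: list[dict], order: dict[str, int]) -> list[dict]:
    """Best-scoring subset of hits that is non-overlapping and colinear.

    Weighted longest-increasing-subsequence DP over hits sorted by exon
    order; locus intervals must be strictly increasing.
    """
    hits = sorted(raw_hits, key=lambda h: order[h["label"]])
    n = len(hits)
    best = [h["score"] for h in hits]
    prev = [-1] * n
    for j in range(n):
        for i in range(j):
            if hits[i]["end"] <= hits[j]["start"]:
                cand = best[i] + hits[j]["score"]
                if cand > best[j]:
                    best[j] = cand
                    prev[j] = i
    if n == 0:
        return []
    j = max(range(n), key=lambda k: best[k])
    chain = []
    while j != -1:
        chain.append(hits[j])
        j = prev[j]
    return chain[::-1]


def map_exons(
    locus: LocusRecord,
    reference: ExonReference,
    *,
    min_identity: float = 60.0,
    min_coverage: float = 50.0,
    match: float = 2.0,
    mismatch: float = -3.0,
    open_gap: float = -5.0,
    extend_gap: float = -2.0,
) -> list[ExonHit]:
    """Place each reference exon on the locus by affine-gap local alignment.

    An exon counts as mapped at >= ``min_identity`` percent identity over
    >= ``min_coverage`` percent of its length.  Mapped exons are chained
    to the best-scoring colinear, non-overlapping set; unplaced exons are
    simply omitted.  Donor/acceptor dinucleotides are read from the intron
    bases flanking each placement.
    """
    if not locus.sequence:
        raise ValueError("empty locus")
    aligner = _make_aligner(match, mismatch, open_gap, extend_gap)
    raw = []
    for exon in reference.exons:
        hit = _align_exon(aligner, locus.sequence, exon)
        if hit is None:
            continue
        if hit["identity"] < min_identity or hit["coverage"] < min_coverage:
            continue
        raw.append(hit)
    order = {lab: i for i, lab in enumerate(reference.labels)}
    chained = _chain_hits(raw, order)
    seq = locus.sequence
    out = []
    for h in chained:
        out.append(
            ExonHit(
                label=h["label"],
                start=h["start"],
                end=h["end"],
                identity=h["identity"],
                insertions=h["insertions"],
                deletions=h["deletions"],
                donor=seq[h["end"]:h["end"] + 2],
                acceptor=seq[max(h["start"] - 2, 0):h["start"]],
                score=h["score"],
                indels=h["indels"],
            )
        )
    return out


# ---------------------------------------------------------------------------
# super-exon detection
# ---------------------------------------------------------------------------

def detect_super_exon(
    hits: Sequence[ExonHit],
    locus: LocusRecord,
    reference: ExonReference,
    pair: tuple[str, str] = ("11", "12"),
) -> Optional[FusionRecord]:
    """Report an exon fusion with in-frame intron retention, if present.

    A fusion requires (i) a non-canonical donor after the first exon of
    the pair and a non-canonical acceptor before the second, and (ii) an
    intervening segment whose length is a multiple of three and which adds
    no in-frame stop codon to the spliced transcript.
    """
    by_label = {h.label: h for h in hits}
    first = by_label.get(pair[0])
    second = by_label.get(pair[1])
    if first is None or second is None:
        return None
    if first.donor == CANONICAL_DONOR or second.acceptor == CANONICAL_ACCEPTOR:
        return None
    retained = locus.sequence[first.end:second.start]
    if len(retained) % 3 != 0:
        return None
    # scan the codon grid of the spliced transcript for stops introduced by
    # the retained segment (codons overlapping it, junction codons included)
    order = {lab: i for i, lab in enumerate(reference.labels)}
    upstream_len = sum(
        h.end - h.start for h in hits if order[h.label] < order[pair[0]]
    )
    len_first = first.end - first.start
    spliced = locus.sequence[first.start:second.end]
    for pos in range((-upstream_len) % 3, len(spliced) - 2, 3):
        overlaps_retained = pos + 3 > len_first and pos < len_first + len(retained)
        if overlaps_retained and spliced[pos:pos + 3].upper() in STOP_CODONS:
            return None
    return FusionRecord(
        labels=pair,
        retained_length=len(retained),
        inserted_residues=len(retained) // 3,
        start=first.end,
        end=second.start,
    )


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def _reconstruct(
    hits: Sequence[ExonHit],
    locus: LocusRecord,
    reference: ExonReference,
    fusion: Optional[FusionRecord],
) -> tuple[str, list[int], list[int]]:
    """Splice hit segments (plus any retained intron) into a CDS.

    Returns the CDS, the locus coordinate of every CDS base, and the
    cumulative net frame shift in effect at every CDS base.
    """
    cds_chars: list[str] = []
    locus_pos: list[int] = []
    shifts: list[int] = []
    shift = 0
    seq = locus.sequence
    for hit in hits:
        events = sorted(hit.indels, key=lambda e: e[1])
        seg_start = len(cds_chars)
        for i in range(hit.start, hit.end):
            cds_chars.append(seq[i])
            locus_pos.append(i)
            shifts.append(shift)  # refined below per indel
        # apply shifts within the segment
        local = 0
        for kind, pos, length in events:
            delta = length if kind == "ins" else -length
            boundary = seg_start + pos + (length if kind == "ins" else 0)
            for j in range(max(boundary, seg_start), len(cds_chars)):
                shifts[j] += delta
            local += delta
        shift += local
        if fusion is not None and hit.label == fusion.labels[0]:
            # in-frame retained intron: its bases translate as extra codons
            for i in range(fusion.start, fusion.end):
                cds_chars.append(seq[i])
                locus_pos.append(i)
                shifts.append(shift)
            shift += fusion.retained_length  # multiple of 3, frame preserved
    return "".join(cds_chars), locus_pos, shifts


def classify_locus(
    hits: Sequence[ExonHit],
    locus: LocusRecord,
    reference: ExonReference,
    *,
    min_exons: int = 3,
    fusion_pair: tuple[str, str] = ("11", "12"),
    max_n_fraction: float = 0.20,
) -> IntegrityReport:
    """Turn exon placements into an intact/pseudogene/absent verdict.

    The fusion check runs first so a clean in-frame super-exon is not
    double-reported as two splice lesions.  Exons whose placement is more
    than ``max_n_fraction`` ambiguous bases are reported ``unresolved``
    and never contribute lesions.
    """
    order = {lab: i for i, lab in enumerate(reference.labels)}
    hits = sorted(hits, key=lambda h: order[h.label])
    for a, b in itertools.pairwise(hits):
        if a.end > b.start:
            raise ChainingError(
                f"hits for exons {a.label} and {b.label} are out of order"
            )
    if len(hits) < min_exons:
        return IntegrityReport(
            status="absent", lesions=[], fusion=None, cds="", protein="",
            hits=list(hits),
        )

    seq = locus.sequence
    lesions: list[Lesion] = []
    unresolved: list[str] = []
    mapped = {h.label for h in hits}

    resolved_hits = []
    for h in hits:
        segment = h.segment(locus)
        n_frac = segment.upper().count("N") / max(len(segment), 1)
        if n_frac > max_n_fraction:
            unresolved.append(h.label)
        else:
            resolved_hits.append(h)

    fusion = detect_super_exon(hits, locus, reference, pair=fusion_pair)

    # missing exons
    for exon in reference.exons:
        if exon.label not in mapped:
            lesions.append(
                Lesion(kind="exon_missing", start=None, end=None,
                       exon=exon.label, detail="no placement above thresholds")
            )

    # splice sites (terminal exons have none on their outer side)
    first_label = hits[0].label
    last_label = hits[-1].label
    fused = set(fusion.labels) if fusion else set()
    for h in resolved_hits:
        if h.label != last_label and not (fusion and h.label == fusion.labels[0]):
            donor = h.donor.upper()
            if donor != CANONICAL_DONOR and "N" not in donor:
                lesions.append(
                    Lesion(kind="splice_donor_loss", start=h.end,
                           end=h.end + 2, exon=h.label,
                           detail=f"donor {donor} != {CANONICAL_DONOR}")
                )
        if h.label != first_label and not (fusion and h.label == fusion.labels[1]):
            acc = h.acceptor.upper()
            if acc != CANONICAL_ACCEPTOR and "N" not in acc:
                lesions.append(
                    Lesion(kind="splice_acceptor_loss", start=h.start - 2,
                           end=h.start, exon=h.label,
                           detail=f"acceptor {acc} != {CANONICAL_ACCEPTOR}")
                )

    # frameshifts: net indel length per exon not a multiple of 3
    for h in resolved_hits:
        if h.net_shift % 3 != 0:
            pos = h.start + (h.indels[0][1] if h.indels else 0)
            lesions.append(
                Lesion(kind="frameshift", start=pos, end=pos, exon=h.label,
                       detail=f"net indel length {h.net_shift:+d}")
            )

    # premature stops: in-frame stop codons upstream of the reference stop
    cds, locus_pos, shifts = _reconstruct(hits, locus, reference, fusion)
    unresolved_ranges = [
        (h.start, h.end) for h in hits if h.label in unresolved
    ]
    for p in range(0, len(cds) - 5, 3):  # exclude the terminal codon
        codon = cds[p:p + 3].upper()
        if codon not in STOP_CODONS:
            continue
        if shifts[p] % 3 != 0:
            continue  # consequence of an upstream frameshift, not a lesion
        lp = locus_pos[p]
        if any(s <= lp < e for s, e in unresolved_ranges):
            continue
        exon_label = next(
            (h.label for h in hits if h.start <= lp < h.end), "?"
        )
        lesions.append(
            Lesion(kind="premature_stop", start=lp, end=locus_pos[p + 2] + 1,
                   exon=exon_label, detail=f"in-frame {codon}")
        )

    protein = str(Seq(cds[: len(cds) - len(cds) % 3]).translate())
    status = "pseudogene" if lesions else "intact"
    return IntegrityReport(
        status=status,
        lesions=lesions,
        fusion=fusion,
        cds=cds,
        protein=protein,
        unresolved_exons=unresolved,
        hits=list(hits),
    )


def screen_locus(
    locus: LocusRecord,
    reference: ExonReference,
    **kwargs,
) -> IntegrityReport:
    """Convenience wrapper: map exons then classify in one call."""
    map_kw = {k: kwargs.pop(k) for k in (
        "min_identity", "min_coverage", "match", "mismatch",
        "open_gap", "extend_gap",
    ) if k in kwargs}
    hits = map_exons(locus, reference, **map_kw)
    return classify_locus(hits, locus, reference, **kwargs)


# ---------------------------------------------------------------------------
# nomenclature
# ---------------------------------------------------------------------------

def assign_exon_nomenclature(
    n_exons: int,
    tm1_index: int,
    fused_pair: Optional[tuple[int, int]] = None,
) -> list[str]:
    """Standardized exon labels for an *SCNN1* gene.

    The TM1-coding exon is labelled ``2`` and downstream exons follow up
    to ``13``; a single upstream exon is ``1``, several are ``1a, 1b`` ...
    A physically fused exon pair (e.g. ``(11, 12)``) is labelled with an
    asterisk on the lower number (``11*``) and consumes both numbers.
    """
    if not 0 <= tm1_index < n_exons:
        raise ValueError("TM1 exon index outside the exon list")
    upstream = tm1_index
    labels: list[str] = []
    if upstream == 1:
        labels.append("1")
    elif upstream > 1:
        labels.extend("1" + chr(ord("a") + i) for i in range(upstream))
    core = n_exons - upstream
    num = 2
    for _ in range(core):
        if fused_pair and num == fused_pair[0]:
            labels.append(f"{num}*")
            num += 2
        else:
            labels.append(str(num))
            num += 1
    if num - 1 > 13:
        raise NomenclatureError(
            f"labels ran past exon 13 (last label {num - 1})"
        )
    return labels
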