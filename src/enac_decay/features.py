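"""Gene composition metrics: GC content, GC3 and size summaries.

These are the descriptive statistics used to contrast the compact,
GC-rich *SCNN1D* gene with its *SCNN1A/B/G* paralogs: overall G/C
fraction of the gene body (start codon through stop codon), G/C fraction
of the coding sequence, wobble-position GC (GC3) and lengths.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import EmptySequence, FrameError

START_CODONS = frozenset({"ATG"})


@dataclass(frozen=True)
class GeneFeatureRow:
    gene: str
    gene_gc: float        # percent, start codon through stop codon
    gene_size: int        # bases, start codon through stop codon inclusive
    cdna_gc: float        # percent over the coding sequence
    gc3: float            # percent G/C at third codon positions
    coding_length: int    # coding bases (multiple of 3)


def gc_fraction(sequence: str) -> float:
    """Percent G/C among unambiguous bases; ``N`` is excluded entirely."""
    s = sequence.upper()
    gc = s.count("G") + s.count("C")
    acgt = gc + s.count("A") + s.count("T")
    if acgt == 0:
        raise EmptySequence("no unambiguous bases in sequence")
    return 100.0 * gc / acgt


def at_fraction(sequence: str) -> float:
    """Percent A/T among unambiguous bases (complement of :func:`gc_fraction`)."""
    return 100.0 - gc_fraction(sequence)


def gc3(cds: str, *, include_stop: bool = True) -> float:
    """Percent G/C at the third position of each codon.

    The terminal stop codon counts by default; pass ``include_stop=False``
    to drop it.
    """
    s = cds.upper()
    if len(s) % 3 != 0:
        raise FrameError(f"CDS length {len(s)} not a multiple of 3")
    if not include_stop:
        s = s[:-3]
    thirds = s[2::3]
    return gc_fraction(thirds)


def summarize_gene_features(
    gene: str,
    cds: str,
    *,
    name: str = "",
    include_stop: bool = True,
) -> GeneFeatureRow:
    """All Table-style composition metrics for one gene.

    ``gene`` is the genomic span from the designated start codon through
    the stop codon (introns included); ``cds`` is the spliced coding
    sequence, start through stop.
    """
    c = cds.upper()
    if len(c) % 3 != 0:
        raise FrameError(f"CDS length {len(c)} not a multiple of 3")
    if c[:3] not in START_CODONS:
        raise FrameError(f"CDS does not begin with a start codon ({c[:3]})")
    return GeneFeatureRow(
        gene=name,
        gene_gc=gc_fraction(gene),
        gene_size=len(gene),
        cdna_gc=gc_fraction(c),
        gc3=gc3(c, include_stop=include_stop),
        coding_length=len(c),
    )
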