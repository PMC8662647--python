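"""Synthetic data with planted ground truth for every pipeline stage.

Three generators mirror the three kinds of raw input the package
consumes:

* :func:`generate_locus_set` — an anchored chromosome carrying a 12-exon
  gene with an optional plan of ORF lesions and/or an exon fusion;
* :func:`generate_trace` — a two-electrode voltage-clamp current trace
  with programmed amiloride-sensitive current and sodium self-inhibition;
* :func:`generate_habitat_dataset` — species occurrence records over an
  aridity raster drawn from a gamma random-intercept model.

All generators are pure functions of their spec (which includes the
seed); the seed is split into named substreams so that changing one
component of a spec does not perturb unrelated draws.  Each generator
returns a *truth record* sufficient to assert the consuming module's
output without re-deriving it.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .errors import SpecError
from .habitat import AridityRaster
from .integrity import (
    Anchor,
    ExonReference,
    LocusRecord,
    ReferenceExon,
    STOP_CODONS,
)
from .ephys import Epoch, TevcTrace

_BASES = np.array(list("ACGT"))

# default 12-exon gene model (labels 2..13): exon lengths in nt, roughly
# matching the canonical SCNN1 layout of short internal exons and a long
# terminal exon carrying TM2 and the C-terminus
DEFAULT_EXON_LENGTHS = (120, 90, 150, 141, 126, 156, 102, 84, 90, 63, 99, 300)
DEFAULT_EXON_LABELS = tuple(str(i) for i in range(2, 14))


def _substream(seed: int, label: str) -> np.random.Generator:
    """Deterministic named substream of a master seed.

    Uses a stable digest of the label (Python's builtin ``hash`` is salted
    per process and would break cross-run reproducibility).
    """
    digest = zlib.crc32(label.encode("utf8"))
    child = np.random.SeedSequence([seed, digest])
    return np.random.default_rng(child)


def _random_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=n, p=p)])


def _random_codons(rng: np.random.Generator, n_codons: int, gc: float) -> str:
    """Stop-free random codons at roughly the requested GC content."""
    out = []
    while len(out) < n_codons:
        codon = _random_seq(rng, 3, gc)
        if codon not in STOP_CODONS:
            out.append(codon)
    return "".join(out)


# ---------------------------------------------------------------------------
# locus generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LesionPlan:
    kind: str                 # one of integrity.LESION_KINDS
    exon: str                 # exon label
    offset: int = 0           # nt offset within the exon
    payload: int = -2         # frameshift indel length (negative = deletion)


@dataclass(frozen=True)
class FusionPlan:
    pair: tuple[str, str] = ("11", "12")
    retained_length: int = 15


@dataclass(frozen=True)
class LocusSpec:
    seed: int = 0
    exon_lengths: tuple[int, ...] = DEFAULT_EXON_LENGTHS
    exon_labels: tuple[str, ...] = DEFAULT_EXON_LABELS
    intron_length: tuple[int, int] = (150, 400)
    gc: float = 0.58
    anchor_length: int = 300
    spacer_length: int = 150
    lesions: tuple[LesionPlan, ...] = ()
    fusion: Optional[FusionPlan] = None
    absent: bool = False      # pure random sequence between the anchors
    strand: str = "+"

    def __post_init__(self) -> None:
        if sum(self.exon_lengths) % 3 != 0:
            raise SpecError("total coding length must be a multiple of 3")
        if len(self.exon_lengths) != len(self.exon_labels):
            raise SpecError("exon_lengths and exon_labels disagree")
        seen = set()
        for plan in self.lesions:
            key = (plan.exon, plan.offset)
            if key in seen:
                raise SpecError(f"two lesions at the same offset: {key}")
            seen.add(key)
            if plan.exon not in self.exon_labels:
                raise SpecError(f"lesion exon {plan.exon!r} not in the model")
            if not 0 <= plan.offset < dict(
                zip(self.exon_labels, self.exon_lengths)
            )[plan.exon]:
                raise SpecError("lesion offset outside exon bounds")
        if self.fusion is not None and self.fusion.retained_length % 3 != 0:
            raise SpecError(
                "retained length must be a multiple of 3 for an in-frame fusion"
            )


@dataclass(frozen=True)
class PlantedLesion:
    kind: str
    exon: str
    start: Optional[int]      # locus coordinates (inter-anchor segment)
    end: Optional[int]


@dataclass
class SyntheticLocus:
    chromosome: str
    anchors: tuple[Anchor, Anchor]
    locus: LocusRecord
    reference: ExonReference
    status: str               # intact | pseudogene | absent
    lesions: list[PlantedLesion]
    fusion: Optional[FusionPlan]
    fusion_coords: Optional[tuple[int, int]]
    exon_coords: dict[str, tuple[int, int]]
    cds: str


def _build_gene(rng: np.random.Generator, spec: LocusSpec):
    """Unmutated gene: exon sequences, introns, per-exon phases."""
    n_codons = sum(spec.exon_lengths) // 3
    cds = "ATG" + _random_codons(rng, n_codons - 2, spec.gc) + "TAA"
    exons: list[ReferenceExon] = []
    pos = 0
    for label, length in zip(spec.exon_labels, spec.exon_lengths):
        exons.append(ReferenceExon(label=label, sequence=cds[pos:pos + length],
                                   phase=pos % 3))
        pos += length
    introns = []
    for _ in range(len(exons) - 1):
        ilen = int(rng.integers(spec.intron_length[0], spec.intron_length[1]))
        introns.append("GT" + _random_seq(rng, ilen - 4, 0.5) + "AG")
    return cds, exons, introns


def _stop_free_retained(rng, length, exon_tail, exon_head):
    """Retained-intron sequence introducing no in-frame stop codon.

    ``exon_tail`` holds the upstream-exon bases that open the codon broken
    at the junction (so the scan below starts on a codon boundary), and
    ``exon_head`` the first downstream-exon bases closing the final codon.
    The first/last two bases are forced non-canonical so the ablated
    splice sites are visible to the fusion detector.
    """
    for _ in range(200):
        seq = "CA" + _random_seq(rng, length - 4, 0.5) + "TC"
        window = exon_tail + seq + exon_head
        if not any(
            window[p:p + 3] in STOP_CODONS
            for p in range(0, len(window) - 2, 3)
        ):
            return seq
    raise SpecError("could not draw a stop-free retained intron")


def generate_locus_set(spec: LocusSpec) -> SyntheticLocus:
    """Anchored synthetic locus whose classification truth is the plan."""
    rng_seq = _substream(spec.seed, "sequence")
    rng_les = _substream(spec.seed, "lesions")

    cds, exons, introns = _build_gene(rng_seq, spec)
    reference = ExonReference(exons)

    if spec.absent:
        gene_len = sum(spec.exon_lengths) + sum(len(i) for i in introns)
        gene_parts: list[str] = [_random_seq(rng_seq, gene_len, 0.5)]
        exon_coords: dict[str, tuple[int, int]] = {}
    else:
        gene_parts = []
        exon_coords = {}
        pos = spec.spacer_length
        for i, exon in enumerate(exons):
            gene_parts.append(exon.sequence)
            exon_coords[exon.label] = (pos, pos + len(exon.sequence))
            pos += len(exon.sequence)
            if i < len(introns):
                gene_parts.append(introns[i])
                pos += len(introns[i])

    locus_seq = (
        _random_seq(rng_seq, spec.spacer_length, 0.5)
        + "".join(gene_parts)
        + _random_seq(rng_seq, spec.spacer_length, 0.5)
    )

    lesions: list[PlantedLesion] = []
    fusion_coords = None
    edits: list[tuple[int, int, str]] = []  # (start, end, replacement)

    cum = {lab: sum(spec.exon_lengths[:i])
           for i, lab in enumerate(spec.exon_labels)}

    if spec.fusion is not None and not spec.absent:
        a, b = spec.fusion.pair
        ia = spec.exon_labels.index(a)
        start = exon_coords[a][1]
        end = exon_coords[b][0]
        # upstream-exon bases left over after the last full codon
        tail_len = (cum[a] + spec.exon_lengths[ia]) % 3
        exon_tail = exons[ia].sequence[len(exons[ia].sequence) - tail_len:] if tail_len else ""
        exon_head = exons[ia + 1].sequence[:3]
        retained = _stop_free_retained(
            rng_les, spec.fusion.retained_length, exon_tail, exon_head,
        )
        edits.append((start, end, retained))

    for plan in spec.lesions:
        if spec.absent:
            break
        estart, eend = exon_coords[plan.exon]
        if plan.kind == "premature_stop":
            codon_off = plan.offset + ((3 - (cum[plan.exon] + plan.offset) % 3) % 3)
            if codon_off + 3 > eend - estart:
                codon_off -= 3
            pos = estart + codon_off
            if pos <= estart and plan.exon == spec.exon_labels[0]:
                pos = estart + 3  # never clobber the start codon
            edits.append((pos, pos + 3, "TAA"))
            lesions.append(PlantedLesion("premature_stop", plan.exon, pos, pos + 3))
        elif plan.kind == "frameshift":
            pos = estart + plan.offset
            if plan.payload < 0:
                edits.append((pos, pos - plan.payload, ""))
            else:
                ins = _random_seq(rng_les, plan.payload, 0.5)
                edits.append((pos, pos, ins))
            lesions.append(PlantedLesion("frameshift", plan.exon, pos, pos))
        elif plan.kind == "splice_donor_loss":
            pos = eend
            edits.append((pos, pos + 2, "CA"))
            lesions.append(PlantedLesion("splice_donor_loss", plan.exon, pos, pos + 2))
        elif plan.kind == "splice_acceptor_loss":
            pos = estart - 2
            edits.append((pos, pos + 2, "TC"))
            lesions.append(
                PlantedLesion("splice_acceptor_loss", plan.exon, estart - 2, estart)
            )
        elif plan.kind == "exon_missing":
            pad = 10
            edits.append((estart - pad, eend + pad, ""))
            lesions.append(PlantedLesion("exon_missing", plan.exon, None, None))
        else:
            raise SpecError(f"unknown lesion kind {plan.kind!r}")

    # apply edits right-to-left so stored truth coordinates stay valid
    for start, end, repl in sorted(edits, key=lambda e: -e[0]):
        locus_seq = locus_seq[:start] + repl + locus_seq[end:]

    if spec.fusion is not None and not spec.absent:
        a, b = spec.fusion.pair
        fusion_coords = (exon_coords[a][1],
                         exon_coords[a][1] + spec.fusion.retained_length)

    # NOTE: coordinates of planted lesions downstream of a deletion /
    # insertion shift; plans are applied in descending coordinate order and
    # truth coords refer to the *edited* locus, so adjust upstream-edit sizes
    shift_events = sorted(
        [(s, len(r) - (e - s)) for s, e, r in edits], key=lambda x: x[0]
    )

    def _adjust(pos: Optional[int]) -> Optional[int]:
        if pos is None:
            return None
        delta = sum(d for s, d in shift_events if s < pos)
        return pos + delta

    lesions = [
        PlantedLesion(l.kind, l.exon, _adjust(l.start), _adjust(l.end))
        for l in lesions
    ]
    exon_coords = {
        lab: (_adjust(s), _adjust(e)) for lab, (s, e) in exon_coords.items()
    }
    if fusion_coords is not None:
        start = exon_coords[spec.fusion.pair[0]][1]
        fusion_coords = (start, start + spec.fusion.retained_length)

    up = Anchor("UBE2J2", 0, spec.anchor_length, spec.strand)
    down = Anchor(
        "ACAP3",
        spec.anchor_length + len(locus_seq),
        2 * spec.anchor_length + len(locus_seq),
        spec.strand,
    )
    anchor_up_seq = _random_seq(rng_seq, spec.anchor_length, 0.5)
    anchor_down_seq = _random_seq(rng_seq, spec.anchor_length, 0.5)
    chromosome = anchor_up_seq + locus_seq + anchor_down_seq

    if spec.strand == "-":
        from Bio.Seq import Seq

        n = len(chromosome)
        chromosome = str(Seq(chromosome).reverse_complement())
        up = Anchor("UBE2J2", n - up.end, n - up.start, "-")
        down = Anchor("ACAP3", n - down.end, n - down.start, "-")

    locus = LocusRecord(
        species="synthetic",
        assembly=f"sim_{spec.seed}",
        sequence=locus_seq,
        strand=spec.strand,
        region_start=spec.anchor_length,
        region_end=spec.anchor_length + len(locus_seq),
        anchors=(up, down),
    )

    if spec.absent:
        status = "absent"
    elif lesions:
        status = "pseudogene"
    else:
        status = "intact"

    return SyntheticLocus(
        chromosome=chromosome,
        anchors=(up, down),
        locus=locus,
        reference=reference,
        status=status,
        lesions=lesions,
        fusion=spec.fusion,
        fusion_coords=fusion_coords,
        exon_coords=exon_coords,
        cds=cds,
    )


# ---------------------------------------------------------------------------
# trace generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TraceSpec:
    seed: int = 0
    leak_current: float = -0.2      # µA, drug- and Na-insensitive
    delta_ami: float = -6.03        # µA, amiloride-sensitive current at 90 mM
    ssi_percent: float = 46.52      # programmed SSI magnitude
    delta_peak: Optional[float] = None  # peak response on the Na switch (µA)
    tau: float = 30.0               # decay time constant, s
    peak_plateau: float = 2.0       # s the peak holds before decaying
    noise_sd: float = 0.05          # µA Gaussian noise
    sample_rate: float = 10.0       # Hz
    low_na: float = 1.0             # mM
    high_na: float = 90.0           # mM
    low_na_leak_fraction: float = 0.02  # residual ENaC current at low Na

    def __post_init__(self) -> None:
        if not 0.0 <= self.ssi_percent < 100.0:
            raise SpecError("SSI target must be in [0, 100)")
        if self.noise_sd < 0:
            raise SpecError("noise SD must be non-negative")


@dataclass
class SyntheticTrace:
    trace: TevcTrace
    delta_ami: float
    ssi_percent: float
    delta_peak: float


def generate_trace(spec: TraceSpec) -> SyntheticTrace:
    """Piecewise TEVC trace with programmed amiloride block and SSI.

    Epochs: high-Na baseline, amiloride block, washout, low-Na reference,
    then a low-to-high Na switch whose response peaks instantaneously,
    holds a short plateau and decays single-exponentially, calibrated so
    the current 180 s after the switch yields the SSI target exactly at
    zero noise.
    """
    rng = _substream(spec.seed, "trace")
    dt = 1.0 / spec.sample_rate
    dpk = spec.delta_peak if spec.delta_peak is not None else spec.delta_ami

    leak = spec.leak_current
    i_free = leak + spec.delta_ami
    i_low = leak + spec.low_na_leak_fraction * spec.delta_ami

    segs = [
        (60.0, spec.high_na, "none", 0.0),
        (60.0, spec.high_na, "amiloride", 100.0),
        (60.0, spec.high_na, "none", 0.0),
        (60.0, spec.low_na, "none", 0.0),
        (300.0, spec.high_na, "none", 0.0),
    ]
    t0 = 0.0
    epochs = []
    for dur, na, drug, conc in segs:
        epochs.append(Epoch(start=t0, end=t0 + dur, na_mM=na, drug=drug,
                            conc=conc))
        t0 += dur
    total = t0
    time = np.arange(0.0, total, dt)
    current = np.empty_like(time)

    s = spec.ssi_percent / 100.0
    e180 = math.exp(-(180.0 - spec.peak_plateau) / spec.tau)
    plateau_frac = (1.0 - s - e180) / (1.0 - e180)

    for epoch, (dur, na, drug, conc) in zip(epochs, segs):
        m = (time >= epoch.start) & (time < epoch.end)
        t_rel = time[m] - epoch.start
        if drug == "amiloride":
            current[m] = leak
        elif na == spec.low_na:
            current[m] = i_low
        elif epoch is epochs[-1]:
            decay = np.where(
                t_rel <= spec.peak_plateau,
                1.0,
                plateau_frac + (1.0 - plateau_frac)
                * np.exp(-(t_rel - spec.peak_plateau) / spec.tau),
            )
            current[m] = i_low + dpk * decay
        else:
            current[m] = i_free

    if spec.noise_sd > 0:
        current = current + rng.normal(0.0, spec.noise_sd, size=current.shape)

    trace = TevcTrace(time=time, current=current, epochs=epochs)
    return SyntheticTrace(
        trace=trace,
        delta_ami=spec.delta_ami,
        ssi_percent=spec.ssi_percent,
        delta_peak=dpk,
    )


# ---------------------------------------------------------------------------
# habitat generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HabitatSpec:
    seed: int = 0
    n_species: int = 40
    obs_per_species: int = 200
    gamma_shape: float = 4.0
    species_sd: float = 0.53        # random-intercept SD on the log scale
    beta: float = 0.0               # gene-presence effect on log aridity
    intercept: float = math.log(0.45)
    cellsize: float = 0.05          # degrees; > 2 x the 0.02 deg radius
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        if self.gamma_shape <= 0:
            raise SpecError("gamma shape must be positive")
        if self.n_species < 1 or self.obs_per_species < 1:
            raise SpecError("counts must be >= 1")


@dataclass
class SyntheticHabitat:
    occurrences: pd.DataFrame        # species, decimalLatitude/Longitude, year
    species_meta: pd.DataFrame       # species, clade, gene_present, invasive
    raster: AridityRaster
    aridity: np.ndarray              # per-observation drawn AI, row-aligned
    species_effects: np.ndarray      # drawn random intercepts
    spec: HabitatSpec


CLADES = ("Sciuromorpha", "Supramyomorpha", "Hystricomorpha")


def generate_habitat_dataset(spec: HabitatSpec) -> SyntheticHabitat:
    """Occurrences plus a raster painted so median extraction is exact.

    Per-species mean aridity follows ``exp(intercept + beta * gene +
    b_species)`` with gamma-distributed observations around it.  Each
    observation is placed at the centre of its own raster cell and the
    cell carries exactly the drawn aridity value, so
    :func:`~enac_decay.habitat.extract_median_aridity` at radius 0.02 deg
    returns the draw unchanged.
    """
    rng_eff = _substream(spec.seed, "effects")
    rng_obs = _substream(spec.seed, "observations")

    n = spec.n_species * spec.obs_per_species
    species = [f"sp{i:03d}" for i in range(spec.n_species)]
    gene = np.arange(spec.n_species) % 2
    clade = [CLADES[i % 3] for i in range(spec.n_species)]
    effects = rng_eff.normal(0.0, spec.species_sd, size=spec.n_species)
    mu = np.exp(spec.intercept + spec.beta * gene + effects)

    sp_idx = np.repeat(np.arange(spec.n_species), spec.obs_per_species)
    ai = rng_obs.gamma(spec.gamma_shape,
                       mu[sp_idx] / spec.gamma_shape, size=n)

    side = math.ceil(math.sqrt(n))
    values = np.full((side, side), spec.nodata)
    cells = np.arange(n)
    rows, cols = divmod(cells, side)
    values[rows, cols] = ai
    cs = spec.cellsize
    # row 0 is the top (northernmost) row, ESRI grid convention
    lon = (cols + 0.5) * cs
    lat = (side - 1 - rows + 0.5) * cs
    raster = AridityRaster(xll=0.0, yll=0.0, cellsize=cs, values=values,
                           nodata=spec.nodata)

    occurrences = pd.DataFrame(
        {
            "species": np.array(species)[sp_idx],
            "decimalLatitude": lat,
            "decimalLongitude": lon,
            "year": rng_obs.integers(1950, 2021, size=n),
        }
    )
    species_meta = pd.DataFrame(
        {
            "species": species,
            "clade": clade,
            "gene_present": gene.astype(bool),
            "invasive": False,
        }
    )
    return SyntheticHabitat(
        occurrences=occurrences,
        species_meta=species_meta,
        raster=raster,
        aridity=ai,
        species_effects=effects,
        spec=spec,
    )
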