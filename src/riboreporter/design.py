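"""Cloning arithmetic for the riboswitch reporter backbone.

The backbone architecture places two multiple cloning sites around the
promoter slot (MCS1: CsiI-XmaJI-SacI; MCS2: NcoI-SdaI-ScaI) and a type IIS
AarI site whose cut lands immediately after the 2nd nucleotide of the
reporter ORF's 2nd codon.  Double digests (e.g. SacI+NcoI for a promoter,
ScaI+AarI for a 5'UTR) excise a slot whose flanking backbone sequence
doubles as the Gibson-assembly homology: 17 nt on the left, 21-24 nt on the
right by default.  Because the AarI cut reaches into codon 2, a regulatory
element can be fused translationally to the reporter with no scar and any
chosen start codon.

Coordinates are 0-based, half-open, on the top strand.  A cut at coordinate
c separates seq[:c] from seq[c:].  Enzyme cut offsets are stored as
distances from the recognition-site start on the strand the enzyme reads;
for type IIS enzymes they simply exceed the recognition length.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq

from .errors import ConfigError, DataError

__all__ = [
    "Enzyme",
    "Site",
    "CutPositions",
    "OverlapDesign",
    "FusionDesign",
    "InsertReport",
    "load_enzymes",
    "scan_sites",
    "cut_positions",
    "digest",
    "derive_overlaps",
    "with_overlaps",
    "assemble",
    "design_translational_fusion",
    "validate_insert",
]

_DNA = set("ACGT")
_START_CODONS = {"ATG", "GTG", "TTG"}  # common bacterial initiators


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme: IUPAC recognition plus signed cut offsets.

    ``cut_top``/``cut_bottom`` are measured from the recognition start on
    the enzyme's reading strand; offsets beyond ``len(recognition)`` denote
    type IIS downstream cutting.
    """

    name: str
    recognition: str
    cut_top: int
    cut_bottom: int

    def __post_init__(self):
        rec = self.recognition.upper()
        if not rec or any(b not in ambiguous_dna_values for b in rec):
            raise ConfigError(f"{self.name}: recognition must be non-empty IUPAC DNA")
        object.__setattr__(self, "recognition", rec)

    @property
    def is_palindromic(self) -> bool:
        return self.recognition == str(Seq(self.recognition).reverse_complement())

    @property
    def span(self) -> int:
        """Top-strand footprint from recognition start to the farthest cut."""
        return max(len(self.recognition), self.cut_top, self.cut_bottom)


@dataclass(frozen=True)
class Site:
    """A recognition match: top-strand start of the match, and the strand
    the enzyme reads ('+' top, '-' bottom)."""

    start: int
    strand: str


@dataclass(frozen=True)
class CutPositions:
    """Absolute cut coordinates (top-strand numbering) for one site."""

    top: int
    bottom: int


@dataclass(frozen=True)
class OverlapDesign:
    """Gibson-overlap arithmetic for one double digestion of a backbone.

    The excision spans [excision_start, excision_end) on the backbone top
    strand; the overlaps are the exact flanking backbone substrings.
    """

    left_overlap: str
    right_overlap: str
    excision_start: int
    excision_end: int

    @property
    def left_len(self) -> int:
        return len(self.left_overlap)

    @property
    def right_len(self) -> int:
        return len(self.right_overlap)


def load_enzymes(path=None) -> dict[str, Enzyme]:
    """Load an enzyme table (TSV: name, recognition, cut_top, cut_bottom).

    Without ``path`` the packaged REBASE-derived table for the backbone's
    enzymes (CsiI, XmaJI, SacI, NcoI, SdaI, ScaI, AarI) is used; users may
    supply their own file in the same format.
    """
    if path is None:
        text = resources.files("riboreporter.data").joinpath("enzymes.tsv").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    if header[:4] != ["name", "recognition", "cut_top", "cut_bottom"]:
        raise ConfigError("enzyme table must have columns name/recognition/cut_top/cut_bottom")
    out: dict[str, Enzyme] = {}
    for ln in lines[1:]:
        name, rec, top, bottom = ln.split("\t")[:4]
        if name in out:
            raise ConfigError(f"enzyme {name} listed twice")
        out[name] = Enzyme(name=name, recognition=rec, cut_top=int(top), cut_bottom=int(bottom))
    return out


def _check_dna(seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - _DNA
    if bad:
        raise DataError(f"non-DNA characters in sequence: {sorted(bad)}")
    return seq


def _iupac_regex(recognition: str) -> re.Pattern:
    parts = []
    for base in recognition:
        expansion = ambiguous_dna_values[base]
        parts.append(base if len(expansion) == 1 else f"[{expansion}]")
    return re.compile("(?=" + "".join(parts) + ")")  # lookahead: overlapping matches


def scan_sites(seq: str, enzyme: Enzyme, circular: bool = False) -> list[Site]:
    """All recognition matches on both strands, IUPAC degeneracy honored.

    Reverse-strand sites are reported by the top-strand start of the
    reverse-complement match.  Palindromic recognitions are reported once
    (strand '+').  Circular sequences are scanned across the origin;
    positions are reduced mod the sequence length.
    """
    seq = _check_dna(seq)
    n = len(seq)
    rec = enzyme.recognition
    if n < len(rec):
        return []
    search = seq + seq[: len(rec) - 1] if circular else seq

    sites = [Site(m.start() % n, "+") for m in _iupac_regex(rec).finditer(search)]
    if not enzyme.is_palindromic:
        rc = str(Seq(rec).reverse_complement())
        sites += [Site(m.start() % n, "-") for m in _iupac_regex(rc).finditer(search)]
    return sorted(set(sites), key=lambda s: (s.start, s.strand))


def cut_positions(seq: str, enzyme: Enzyme, site: Site, circular: bool = False) -> CutPositions:
    """Absolute top/bottom-strand cut coordinates for one site.

    For a '-' strand site the enzyme reads the bottom strand, so its cuts
    mirror through the match: our top-strand cut is the enzyme's bottom cut.
    Linear sequences reject cuts that fall outside the molecule.
    """
    seq = _check_dna(seq)
    n = len(seq)
    L = len(enzyme.recognition)
    if site.strand == "+":
        top = site.start + enzyme.cut_top
        bottom = site.start + enzyme.cut_bottom
    elif site.strand == "-":
        top = site.start + L - enzyme.cut_bottom
        bottom = site.start + L - enzyme.cut_top
    else:
        raise DataError(f"bad strand {site.strand!r}")
    if circular:
        return CutPositions(top % n, bottom % n)
    if not (0 <= top <= n and 0 <= bottom <= n):
        raise DataError(
            f"{enzyme.name} cut at {top}/{bottom} falls outside linear sequence of length {n}"
        )
    return CutPositions(top, bottom)


def digest(seq: str, enzymes: list[Enzyme] | Enzyme, circular: bool = False) -> list[str]:
    """Fragments of a digestion, computed from top-strand cut coordinates.

    Fragment lengths always sum to the parent length; an uncut molecule is
    returned whole.
    """
    seq = _check_dna(seq)
    if isinstance(enzymes, Enzyme):
        enzymes = [enzymes]
    cuts = sorted(
        {
            cut_positions(seq, e, s, circular=circular).top
            for e in enzymes
            for s in scan_sites(seq, e, circular=circular)
        }
    )
    if not cuts:
        return [seq]
    if circular:
        rotated = seq[cuts[0] :] + seq[: cuts[0]]
        rel = [c - cuts[0] for c in cuts] + [len(seq)]
        return [rotated[a:b] for a, b in zip(rel, rel[1:])]
    edges = [0] + cuts + [len(seq)]
    return [seq[a:b] for a, b in zip(edges, edges[1:]) if b > a]


def _unique_cut(seq: str, enzyme: Enzyme, circular: bool) -> int:
    sites = scan_sites(seq, enzyme, circular=circular)
    if len(sites) != 1:
        positions = [(s.start, s.strand) for s in sites]
        raise DataError(
            f"{enzyme.name} must cut exactly once; found {len(sites)} site(s) at {positions}"
        )
    return cut_positions(seq, enzyme, sites[0], circular=circular).top


def derive_overlaps(
    backbone: str,
    left_enzyme: Enzyme,
    right_enzyme: Enzyme,
    overlap_len_left: int = 17,
    overlap_len_right: int = 21,
) -> OverlapDesign:
    """Overlap design for a double digestion of a (linear) backbone.

    Each enzyme must cut exactly once.  The stretch between the two cuts is
    excised; the left overlap is the ``overlap_len_left`` nt of backbone
    immediately 5' of the excision and the right overlap the
    ``overlap_len_right`` nt immediately 3' of it.  Appending these to an
    insert makes it Gibson-compatible with the linearized backbone.
    """
    backbone = _check_dna(backbone)
    if overlap_len_left < 1 or overlap_len_right < 1:
        raise DataError("overlap lengths must be >= 1 nt")
    lc = _unique_cut(backbone, left_enzyme, circular=False)
    rc = _unique_cut(backbone, right_enzyme, circular=False)
    if lc > rc:
        lc, rc = rc, lc
    if lc == rc:
        raise DataError("the two cuts coincide; nothing to excise")
    if lc - overlap_len_left < 0 or rc + overlap_len_right > len(backbone):
        raise DataError("overlap extends past the end of the backbone")
    return OverlapDesign(
        left_overlap=backbone[lc - overlap_len_left : lc],
        right_overlap=backbone[rc : rc + overlap_len_right],
        excision_start=lc,
        excision_end=rc,
    )


def with_overlaps(design: OverlapDesign, insert: str) -> str:
    """The PCR product to order: insert flanked by its Gibson overlaps."""
    return design.left_overlap + _check_dna(insert) + design.right_overlap


def assemble(backbone: str, design: OverlapDesign, insert: str) -> str:
    """In-silico Gibson assembly of the digested backbone with an insert.

    The homology arms anneal to the backbone flanks and collapse into
    single copies, so the product is the backbone with the excised stretch
    replaced by the insert.
    """
    backbone = _check_dna(backbone)
    insert = _check_dna(insert)
    left_ctx = backbone[design.excision_start - design.left_len : design.excision_start]
    right_ctx = backbone[design.excision_end : design.excision_end + design.right_len]
    if left_ctx != design.left_overlap or right_ctx != design.right_overlap:
        raise DataError("overlap design does not match this backbone")
    return backbone[: design.excision_start] + insert + backbone[design.excision_end :]


@dataclass(frozen=True)
class FusionDesign:
    """A scar-free translational fusion of a regulatory element to the
    reporter ORF: the insert to clone and the resulting fused ORF."""

    insert: str
    fused_orf: str
    report: dict = field(default_factory=dict)


def design_translational_fusion(
    regulatory_element: str, start_codon: str, luxc: str
) -> FusionDesign:
    """Fuse a regulatory element directly to the reporter ORF, scar-free.

    The backbone's type IIS cut ends immediately after the 2nd nucleotide of
    the reporter's codon 2, so the insert must carry the element, the chosen
    start codon (non-ATG starts allowed) and the first 2 nt of codon 2 to
    regenerate the junction.  The report verifies that no nucleotides
    separate the element from the start codon and that the fused ORF reads
    the chosen start followed by the reporter's codons 2..end, in frame.
    """
    element = _check_dna(regulatory_element)
    start = _check_dna(start_codon)
    orf = _check_dna(luxc)
    if len(start) != 3:
        raise DataError(f"start codon must be a 3-mer, got {start!r}")
    if len(orf) < 6 or len(orf) % 3 != 0:
        raise DataError("reporter ORF must be >= 6 nt and a multiple of 3")
    if orf[:3] not in _START_CODONS:
        raise DataError(f"reporter ORF does not begin with a start codon ({orf[:3]})")

    insert = element + start + orf[3:5]
    fused_orf = start + orf[3:]
    if len(fused_orf) % 3 != 0:
        raise DataError("assembly breaks the reading frame")
    fused_aa = str(Seq(fused_orf).translate())
    ref_aa = str(Seq(orf).translate())
    if fused_aa[1:] != ref_aa[1:]:
        raise DataError("fused ORF does not preserve reporter codons 2..end")
    return FusionDesign(
        insert=insert,
        fused_orf=fused_orf,
        report={
            "element_to_start_gap_nt": 0,
            "start_codon": start,
            "codon2": fused_orf[3:6],
            "in_frame": True,
            "fused_protein": fused_aa,
        },
    )


@dataclass(frozen=True)
class InsertReport:
    """PASS/WARN/FAIL verdict for an insert, with reasons."""

    status: str
    messages: tuple[str, ...] = ()


def validate_insert(
    insert: str, enzymes: list[Enzyme] | None = None, min_len: int = 40
) -> InsertReport:
    """Screen an insert before ordering primers.

    Inserts below ``min_len`` (default 40 bp; very short fragments, e.g.
    18-21 bp, assemble poorly by Gibson) FAIL.  Internal recognition sites
    of any backbone enzyme WARN — the insert would need domestication
    before that enzyme could be reused.
    """
    insert = _check_dna(insert)
    if len(insert) < min_len:
        return InsertReport(
            status="FAIL",
            messages=(f"insert is {len(insert)} bp; < {min_len} bp is too short for assembly",),
        )
    warnings = []
    for e in enzymes or []:
        hits = scan_sites(insert, e)
        if hits:
            warnings.append(
                f"internal {e.name} site(s) at {[s.start for s in hits]}; domestication needed"
            )
    if warnings:
        return InsertReport(status="WARN", messages=tuple(warnings))
    return InsertReport(status="PASS")
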