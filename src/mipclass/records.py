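"""Core record types shared across the pipeline.

Coordinates are 1-based and inclusive throughout, matching the residue
numbering convention of the structural literature (e.g. "F56" means the
phenylalanine at position 56 of HsAQP1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
GAP = "-"

#: Subfamily vocabulary. PIP/GIP/MIPE/LIP are assignable to queries; the
#: remaining labels only occur as generator truth or reference annotation.
SUBFAMILIES = ("PIP", "GIP", "MIPE", "LIP", "SIP", "MIPC", "bacterial", "unclassified")


def check_protein(residues: str, where: str = "sequence") -> str:
    """Validate that *residues* uses only the 20 standard amino-acid letters."""
    bad = set(residues) - set(AMINO_ACIDS)
    if bad:
        raise ValueError(
            f"non-standard amino-acid letter(s) {sorted(bad)} in {where}; "
            f"only {AMINO_ACIDS} are accepted"
        )
    return residues


@dataclass(frozen=True)
class MIPSequence:
    """One protein record."""

    seq_id: str
    residues: str
    organism: str = ""

    def __post_init__(self) -> None:
        check_protein(self.residues, where=self.seq_id)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class MIPTemplate:
    """A template protein with planted, mutation-protected landmark sites.

    ``box1_start``/``box2_start`` are the 1-based starts of the two NPA-like
    tripeptide boxes (loop B and loop E); ``h2_pos``, ``h5_pos``, ``le1_pos``,
    ``le2_pos`` locate the four ar/R selectivity-filter residues.
    """

    template_id: str
    residues: str
    box1_start: int
    box2_start: int
    h2_pos: int
    h5_pos: int
    le1_pos: int
    le2_pos: int
    subfamily_label: str

    def __post_init__(self) -> None:
        check_protein(self.residues, where=self.template_id)
        n = len(self.residues)
        if not 200 <= n <= 350:
            raise ValueError(f"template {self.template_id} length {n} outside [200, 350]")
        if not self.box1_start < self.box2_start:
            raise ValueError("box1_start must precede box2_start")
        for name in ("box1_start", "box2_start", "h2_pos", "h5_pos", "le1_pos", "le2_pos"):
            p = getattr(self, name)
            if not 1 <= p <= n:
                raise ValueError(f"{name}={p} outside sequence of length {n}")
        if self.box2_start + 2 > n:
            raise ValueError("second box extends past sequence end")
        # LE1/LE2 sit in the loop-E box context, just downstream of box 2.
        for name in ("le1_pos", "le2_pos"):
            p = getattr(self, name)
            if not self.box2_start < p <= self.box2_start + 6:
                raise ValueError(f"{name}={p} not within 6 residues downstream of box2_start")
        if self.subfamily_label not in SUBFAMILIES:
            raise ValueError(f"unknown subfamily label {self.subfamily_label!r}")

    @property
    def filter_string(self) -> str:
        r = self.residues
        return r[self.h2_pos - 1] + r[self.h5_pos - 1] + r[self.le1_pos - 1] + r[self.le2_pos - 1]

    @property
    def box1(self) -> str:
        return self.residues[self.box1_start - 1 : self.box1_start + 2]

    @property
    def box2(self) -> str:
        return self.residues[self.box2_start - 1 : self.box2_start + 2]


@dataclass(frozen=True)
class SimTruth:
    """Planted truth for one simulated sequence.

    ``true_alignment_row`` (the gapped query) and ``true_template_row`` (the
    gapped template) have equal length and together form the true pairwise
    alignment of the simulated sequence against its source template;
    ungapping ``true_alignment_row`` reproduces the sequence exactly.
    Coordinate fields are 1-based positions in the *mutated* sequence.
    """

    seq_id: str
    source_template_id: str
    planted_box1: str
    planted_box2: str
    planted_filter: str
    planted_cterm: str
    true_alignment_row: str
    true_template_row: str
    subfamily_label: str
    box1_start: int
    box2_start: int
    h2_pos: int
    h5_pos: int
    le1_pos: int
    le2_pos: int


@dataclass(frozen=True)
class NpaBox:
    """One detected NPA-like box (N-[PG]-X tripeptide)."""

    motif: str
    start: int
    which: str  # "first" | "second"

    def __post_init__(self) -> None:
        if len(self.motif) != 3 or self.motif[0] != "N" or self.motif[1] not in "PG":
            raise ValueError(f"{self.motif!r} is not an N-[PG]-X tripeptide")
        if self.which not in ("first", "second"):
            raise ValueError("which must be 'first' or 'second'")


@dataclass(frozen=True)
class NpaBoxPair:
    """The detected pair of NPA-like boxes for one sequence."""

    seq_id: str
    first: NpaBox | None
    second: NpaBox | None
    warnings: tuple[str, ...] = ()

    @property
    def conserved_pair(self) -> bool:
        return (
            self.first is not None
            and self.second is not None
            and self.first.motif == "NPA"
            and self.second.motif == "NPA"
        )


@dataclass(frozen=True)
class ReferenceAnnotation:
    """A reference protein with annotated ar/R filter positions."""

    ref_id: str
    residues: str
    h2_pos: int
    h5_pos: int
    le1_pos: int
    le2_pos: int
    description: str = ""

    def __post_init__(self) -> None:
        check_protein(self.residues, where=self.ref_id)
        n = len(self.residues)
        for name in ("h2_pos", "h5_pos", "le1_pos", "le2_pos"):
            p = getattr(self, name)
            if not 1 <= p <= n:
                raise ValueError(f"{name}={p} outside reference of length {n}")

    @property
    def filter_string(self) -> str:
        r = self.residues
        return r[self.h2_pos - 1] + r[self.h5_pos - 1] + r[self.le1_pos - 1] + r[self.le2_pos - 1]


@dataclass(frozen=True)
class PairwiseAlignment:
    """A global pairwise alignment (query on top, reference below)."""

    gapped_query: str
    gapped_ref: str
    score: float

    def __post_init__(self) -> None:
        if len(self.gapped_query) != len(self.gapped_ref):
            raise ValueError("aligned rows differ in length")
        for q, r in zip(self.gapped_query, self.gapped_ref):
            if q == GAP and r == GAP:
                raise ValueError("gap-gap column in alignment")


@dataclass(frozen=True)
class ArRFilter:
    """The four ar/R selectivity-filter residues of a query.

    Roles in order: H2, H5, LE1, LE2.  A role whose reference position maps
    to a gap column carries the gap marker '-' and no query coordinate.
    """

    seq_id: str
    h2: str
    h5: str
    le1: str
    le2: str
    mapped_positions: tuple[int | None, int | None, int | None, int | None]
    ref_id: str = ""
    low_confidence: bool = False

    @property
    def filter_string(self) -> str:
        return self.h2 + self.h5 + self.le1 + self.le2

    @property
    def complete(self) -> bool:
        return GAP not in self.filter_string


@dataclass(frozen=True)
class SpecificityCall:
    """Substrate-specificity inference from a 4-letter ar/R filter."""

    filter_string: str
    specificity: str  # "water" | "glycerol permease" | "unknown"
    rule_id: str


@dataclass(frozen=True)
class LipSignature:
    """The five LIP diagnostic features; the primary criterion is
    LE1 = P together with LE2 in {L, I}."""

    le1_is_P: bool
    le2_in_LI: bool
    second_box_NPM: bool
    cterm_K: bool
    h2_in_WY: bool

    @property
    def primary(self) -> bool:
        return self.le1_is_P and self.le2_in_LI


@dataclass(frozen=True)
class SubfamilyCall:
    """Final per-sequence subfamily assignment with its evidence trail."""

    seq_id: str
    subfamily: str  # PIP | GIP | MIPE | LIP | unclassified
    specificity: SpecificityCall
    evidence: tuple[tuple[str, str], ...]
    clade_support: float | None = None

    def __post_init__(self) -> None:
        if self.subfamily not in ("PIP", "GIP", "MIPE", "LIP", "unclassified"):
            raise ValueError(f"unknown subfamily {self.subfamily!r}")
        if not self.evidence:
            raise ValueError("evidence trail must be non-empty")
        if self.subfamily == "LIP" and not any(r == "lip_filter_signature" for r, _ in self.evidence):
            raise ValueError("LIP call must carry the filter-signature evidence item")
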