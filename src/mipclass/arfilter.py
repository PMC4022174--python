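"""ar/R selectivity-filter extraction and substrate-specificity inference.

The aromatic/arginine (ar/R) constriction of a MIP pore is formed by one
residue each from helices H2 and H5 plus two residues of the loop-E region
(LE1, LE2); its composition largely determines whether the channel passes
water or bulkier solutes such as glycerol. Annotated positions on a
reference protein are mapped onto a query through an optimal global pairwise
alignment, and the extracted 4-letter filter is matched against the two
composition rules with experimentally known selectivity: the
aquaporin-like pattern (F-H-[A/C]-R, water) and the glyceroporin-like
pattern (W-V-[A/G]-R, glycerol permease).
"""

from __future__ import annotations

import csv

from Bio import Align
from Bio.Align import substitution_matrices

from .records import (
    GAP,
    ArRFilter,
    MIPSequence,
    PairwiseAlignment,
    ReferenceAnnotation,
    SpecificityCall,
    check_protein,
)

GAP_OPEN = 10.0
GAP_EXTEND = 1.0


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    # affine gaps: a gap of length L costs GAP_OPEN + (L-1)*GAP_EXTEND
    aligner.open_gap_score = -GAP_OPEN
    aligner.extend_gap_score = -GAP_EXTEND
    return aligner


_ALIGNER = None


def align_pairwise(query: str, ref: str) -> PairwiseAlignment:
    """Optimal global (Needleman-Wunsch) alignment under BLOSUM62.

    Affine gap penalties: 10 to open, 1 to extend. Among co-optimal
    alignments the first in the aligner's deterministic traceback order is
    returned, so repeated calls give identical output.
    """
    global _ALIGNER
    if not query or not ref:
        raise ValueError("cannot align an empty sequence")
    check_protein(query, "query")
    check_protein(ref, "reference")
    if _ALIGNER is None:
        _ALIGNER = _aligner()
    alignments = _ALIGNER.align(query, ref)
    best = alignments[0]
    gapped_query, gapped_ref = str(best[0]), str(best[1])
    return PairwiseAlignment(
        gapped_query=gapped_query, gapped_ref=gapped_ref, score=float(best.score)
    )


def map_reference_position(aln: PairwiseAlignment, ref_pos: int) -> tuple[int | None, str]:
    """Map a 1-based reference position through the alignment.

    Returns the 1-based query position and its residue, or (None, '-') when
    the reference position sits opposite a gap.
    """
    seen_ref = 0
    seen_query = 0
    for q, r in zip(aln.gapped_query, aln.gapped_ref):
        if q != GAP:
            seen_query += 1
        if r != GAP:
            seen_ref += 1
            if seen_ref == ref_pos:
                if q == GAP:
                    return None, GAP
                return seen_query, q
    raise ValueError(f"reference position {ref_pos} beyond alignment")


def extract_arr_filter(query: MIPSequence, ref: ReferenceAnnotation) -> ArRFilter:
    """Extract the four ar/R residues of ``query`` via alignment to ``ref``.

    Each annotated reference position maps through the global alignment to a
    query column; a position landing on a gap is reported as '-' and flags
    the whole call low-confidence.
    """
    aln = align_pairwise(query.residues, ref.residues)
    letters = []
    positions = []
    for ref_pos in (ref.h2_pos, ref.h5_pos, ref.le1_pos, ref.le2_pos):
        qpos, letter = map_reference_position(aln, ref_pos)
        positions.append(qpos)
        letters.append(letter)
    return ArRFilter(
        seq_id=query.seq_id,
        h2=letters[0],
        h5=letters[1],
        le1=letters[2],
        le2=letters[3],
        mapped_positions=tuple(positions),
        ref_id=ref.ref_id,
        low_confidence=GAP in letters,
    )


def choose_reference(
    query: MIPSequence, refs: list[ReferenceAnnotation]
) -> ReferenceAnnotation:
    """The reference with the highest global alignment score to the query.

    Ties go to the earliest reference in the provided order (the packaged
    order is HsAQP1, then EcGlpF, then any user references).
    """
    if not refs:
        raise ValueError("empty reference list")
    best = None
    for k, ref in enumerate(refs):
        score = align_pairwise(query.residues, ref.residues).score
        cand = (-score, k)
        if best is None or cand < best[:2]:
            best = (-score, k, ref)
    return best[2]


# specificity rules, in precedence order (mutually exclusive anyway: the H2
# letters W and F are disjoint)
_RULES = (
    ("G", "glycerol permease", lambda f: f[0] == "W" and f[1] == "V" and f[2] in "AG" and f[3] == "R"),
    ("W", "water", lambda f: f[0] == "F" and f[1] == "H" and f[2] in "AC" and f[3] == "R"),
)


def infer_specificity(filt: ArRFilter | str) -> SpecificityCall:
    """Substrate specificity from a 4-letter ar/R filter string.

    Rule G (glycerol permease): W-V-[A/G]-R, the glyceroporin composition.
    Rule W (water): F-H-[A/C]-R, the classical aquaporin composition.
    Anything else, or an incomplete filter containing a gap, is unknown.
    """
    fs = filt if isinstance(filt, str) else filt.filter_string
    if len(fs) != 4:
        raise ValueError(f"filter string {fs!r} is not 4 letters")
    if GAP in fs:
        return SpecificityCall(filter_string=fs, specificity="unknown", rule_id="incomplete")
    for rule_id, specificity, pred in _RULES:
        if pred(fs):
            return SpecificityCall(filter_string=fs, specificity=specificity, rule_id=rule_id)
    return SpecificityCall(filter_string=fs, specificity="unknown", rule_id="none")


def load_reference_table(path) -> list[ReferenceAnnotation]:
    """Read a reference-annotation TSV: ref_id, sequence, h2, h5, le1, le2."""
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh, delimiter="\t"))
    out = []
    for r in rows:
        out.append(
            ReferenceAnnotation(
                ref_id=r["ref_id"],
                residues=r["sequence"],
                h2_pos=int(r["h2"]),
                h5_pos=int(r["h5"]),
                le1_pos=int(r["le1"]),
                le2_pos=int(r["le2"]),
                description=r.get("description", ""),
            )
        )
    return out


def write_reference_table(refs, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["ref_id", "sequence", "h2", "h5", "le1", "le2", "description"])
        for r in refs:
            w.writerow(
                [r.ref_id, r.residues, r.h2_pos, r.h5_pos, r.le1_pos, r.le2_pos, r.description]
            )
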