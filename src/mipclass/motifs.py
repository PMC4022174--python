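"""Detection and classification of the two NPA-like boxes of a MIP.

MIPs carry two short, highly conserved Asn-Pro-Ala ("NPA") boxes on loops B
and E. Subfamily-diagnostic variants replace the third letter (NPM, NPG,
NPT, ...) or, rarely, the second (NGA). The scanner therefore considers
every N-[PG]-X tripeptide a candidate and picks the best-scoring positional
pair rather than requiring exact NPA matches.
"""

from __future__ import annotations

import re

from .records import MIPSequence, NpaBox, NpaBoxPair, check_protein

# N, then P or G, then any standard residue
_CANDIDATE = re.compile(r"(?=(N[PG][ARNDCQEGHILKMFPSTWYV]))")

MIN_SEPARATION = 40


def _candidates(residues: str) -> list[tuple[int, str]]:
    """All (1-based start, motif) N-[PG]-X matches, including overlaps."""
    return [(m.start() + 1, m.group(1)) for m in _CANDIDATE.finditer(residues)]


def _score(motif: str) -> int:
    return 2 if motif == "NPA" else 1


def scan_npa_boxes(seq: MIPSequence, min_separation: int = MIN_SEPARATION) -> NpaBoxPair:
    """Locate the loop-B and loop-E NPA-like boxes of one sequence.

    Candidate boxes are all N-[PG]-X tripeptides. The reported pair (i, j)
    must have i starting within the N-terminal 60% of the sequence, j within
    the C-terminal 60%, and j - i >= ``min_separation``; among admissible
    pairs the one maximizing the summed preference score (exact NPA counts
    2, any other N-[PG]-X counts 1) wins, with ties broken by the smallest
    first then smallest second start. When no admissible pair exists, the
    best lone candidate (if any) is reported on its side of the sequence and
    the other box is absent; nothing is ever fabricated.
    """
    residues = check_protein(seq.residues, where=seq.seq_id)
    n = len(residues)
    if n < 100:
        raise ValueError(f"{seq.seq_id}: sequence shorter than 100 residues")
    cands = _candidates(residues)
    if not cands:
        return NpaBoxPair(
            seq_id=seq.seq_id,
            first=None,
            second=None,
            warnings=("no N-[PG]-X candidate found",),
        )
    first_limit = int(0.6 * n)  # start of first box must be <= this
    second_min = n - int(0.6 * n) + 1  # start of second box must be >= this
    firsts = [(p, m) for p, m in cands if p <= first_limit]
    seconds = [(p, m) for p, m in cands if p >= second_min]
    best = None
    for i, mi in firsts:
        for j, mj in seconds:
            if j - i < min_separation:
                continue
            cand = (-(_score(mi) + _score(mj)), i, j, mi, mj)
            if best is None or cand[:3] < best[:3]:
                best = cand
    if best is not None:
        _, i, j, mi, mj = best
        return NpaBoxPair(
            seq_id=seq.seq_id,
            first=NpaBox(motif=mi, start=i, which="first"),
            second=NpaBox(motif=mj, start=j, which="second"),
        )
    # no admissible pair: report the single best candidate on its side
    ranked = sorted(cands, key=lambda pm: (-_score(pm[1]), pm[0]))
    p, m = ranked[0]
    if p <= first_limit:
        box = NpaBox(motif=m, start=p, which="first")
        return NpaBoxPair(
            seq_id=seq.seq_id, first=box, second=None, warnings=("no admissible box pair",)
        )
    box = NpaBox(motif=m, start=p, which="second")
    return NpaBoxPair(
        seq_id=seq.seq_id, first=None, second=box, warnings=("no admissible box pair",)
    )


def classify_motif_pair(pair: NpaBoxPair) -> str:
    """Label a detected box pair.

    canonical: both boxes NPA; second_NPM: NPA then NPM (the pattern of the
    heterokont LIPs); first_variant: second NPA but a variant first box;
    incomplete: either box absent; other_variant: anything else.
    """
    if pair.first is None or pair.second is None:
        return "incomplete"
    a, b = pair.first.motif, pair.second.motif
    if a == "NPA" and b == "NPA":
        return "canonical"
    if a == "NPA" and b == "NPM":
        return "second_NPM"
    if a != "NPA" and b == "NPA":
        return "first_variant"
    return "other_variant"
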