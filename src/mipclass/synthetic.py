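"""Synthetic MIP-like protein sequences with planted, recoverable truth.

Every sequence this module emits descends from a single master scaffold laid
out as an alignment of 356 columns that mimics MIP architecture: six
transmembrane segments' worth of background residues, two NPA-like boxes
(loop B and loop E), the four ar/R selectivity-filter sites (roles H2, H5,
LE1, LE2), and a planted C-terminal residue. Because panel sequences,
subfamily templates and the packaged reference scaffolds all occupy known
columns of the same master alignment, the true alignment of any pair is
known by construction and downstream motif/filter/tree recovery can be
scored against exact planted truth.

The packaged ``HsAQP1`` and ``EcGlpF`` reference annotations are *synthetic*
scaffolds (no real database sequence is redistributed): they are MIP-shaped
background sequences whose annotated ar/R positions carry exactly the
published residues (F56/H180/C189/R195 for the human aquaporin; W48/G191/
F200/R205 for the E. coli glyceroporin), which is all the extraction
machinery relies on.

Background residues are drawn from the JTT equilibrium amino-acid
frequencies. Outside planted boxes, the N-[PG] bigram is scrubbed from all
backgrounds so that planted NPA-like boxes are the only motif candidates and
recovery statistics are exact.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .phylo import Msa, default_model
from .records import (
    AMINO_ACIDS,
    GAP,
    MIPSequence,
    MIPTemplate,
    ReferenceAnnotation,
    SimTruth,
)

_AA = np.array(list(AMINO_ACIDS))
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

# ---------------------------------------------------------------------------
# Master alignment layout (all coordinates 0-based master columns)

#: residues between/around the four filter columns: [before H2, H2..H5,
#: H5..LE1, LE1..LE2, after LE2] for the widest geometry in each segment
_SEG_SIZES = (59, 142, 12, 5, 134)
_F_COLS = (59, 202, 215, 221)  # H2, H5, LE1, LE2 master columns
MASTER_LEN = sum(_SEG_SIZES) + 4  # 356

_BOX1_COLS = (94, 95, 96)
_BOX2_COLS = (212, 213, 214)

#: conserved anchor columns take letters from this cycle (indexed by master
#: column), so nearby anchors are always distinct and a register shift around
#: a filter column loses every anchor match. The cycle avoids N/P/G (no
#: spurious motif candidates) and the letters of the planted boxes and of
#: common filter compositions (A, M, C, I, L, V), making anchors unambiguous.
_ANCHOR_CYCLE = "WDKEHQFRTSY"

# geometry = residue counts per segment, in master order
_PANEL_COUNTS = (59, 129, 12, 2, 134)  # length 340
_HSAQP1_COUNTS = (55, 123, 8, 5, 74)  # length 269, filters at 56/180/189/195
_ECGLPF_COUNTS = (47, 142, 8, 4, 76)  # length 281, filters at 48/191/200/205

_SCAFFOLD_SEED = 53201
_TEMPLATE_SEED = 90407
_REFERENCE_SEED = 61807

#: panel landmark positions in (1-based) sequence coordinates; stable for
#: every panel member because length trimming removes only columns between
#: the LE2 flank and the C-terminal tail
PANEL_H2, PANEL_H5, PANEL_LE1, PANEL_LE2 = 60, 190, 203, 206
PANEL_BOX1, PANEL_BOX2 = 95, 200


def _segment_ranges():
    out = []
    start = 0
    for k, size in enumerate(_SEG_SIZES):
        out.append((start, start + size))
        start += size + 1  # skip the filter column (none after the last seg)
    return out


_SEG_RANGES = _segment_ranges()


def _occupancy(counts) -> list[int]:
    """Master columns occupied by a geometry, in sequence order."""
    cols: list[int] = []
    for k, ((a, b), need) in enumerate(zip(_SEG_RANGES, counts)):
        size = b - a
        if need > size:
            raise ValueError("segment overflow")
        # Segments before a filter column keep their last residues against
        # that column (conserved right-anchor). The short LE1..LE2 segment
        # keeps one residue against LE2 and the rest against LE1, so both
        # filter columns are flanked by conserved matches and length
        # differences between geometries gap strictly between the anchors.
        # The C-terminal tail is head-aligned against LE2.
        if k == 3:
            tail = 1 if need else 0
        elif k == 4:
            tail = 0
        else:
            tail = min(need, 5)
        head = need - tail
        cols.extend(range(a, a + head))
        cols.extend(range(b - tail, b))
        if k < 4:
            cols.append(_F_COLS[k])
    return cols


_PANEL_COLS = _occupancy(_PANEL_COUNTS)
_HS_COLS = _occupancy(_HSAQP1_COUNTS)
_EC_COLS = _occupancy(_ECGLPF_COUNTS)


def _conserved_columns() -> frozenset[int]:
    out = set()
    for f in _F_COLS:
        out.update(range(f - 5, f + 6))
    out.update(range(91, 100))  # loop-B box flank
    out.difference_update(_F_COLS)
    out.difference_update(_BOX1_COLS)
    out.difference_update(_BOX2_COLS)
    return frozenset(c for c in out if 0 <= c < MASTER_LEN)


_CONSERVED = _conserved_columns()
_PLANTED_MASTER = set(_F_COLS) | set(_BOX1_COLS) | set(_BOX2_COLS)


def _scrub_bigram(letters: list[str], immutable, rng, planted_n_positions=frozenset()):
    """Remove N-[PG] bigrams outside planted boxes.

    ``letters`` are consecutive residues; positions in ``immutable`` keep
    their letter, in which case the partner of the bigram is redrawn.
    ``planted_n_positions`` are indices whose 'N' starts a planted box and is
    therefore a legitimate motif candidate.
    """
    for i in range(len(letters) - 1):
        if letters[i] != "N" or letters[i + 1] not in "PG" or i in planted_n_positions:
            continue
        if i + 1 not in immutable:
            choices = [a for a in AMINO_ACIDS if a not in "NPG" and a != letters[i + 1]]
            letters[i + 1] = choices[rng.integers(len(choices))]
        elif i not in immutable:
            choices = [a for a in AMINO_ACIDS if a != "N"]
            letters[i] = choices[rng.integers(len(choices))]
        # both immutable can only happen inside a planted box, excluded above


def _draw_background(n: int, rng) -> list[str]:
    pi = default_model().pi
    return list(_AA[rng.choice(20, size=n, p=pi / pi.sum())])


def _master_scaffold() -> list[str]:
    """The fixed ancestral residue per master column."""
    rng = np.random.default_rng(_SCAFFOLD_SEED)
    letters = _draw_background(MASTER_LEN, rng)
    for c in sorted(_CONSERVED):
        letters[c] = _ANCHOR_CYCLE[c % len(_ANCHOR_CYCLE)]
    _scrub_bigram(letters, immutable=_CONSERVED | _PLANTED_MASTER, rng=rng)
    return letters


_SCAFFOLD_CACHE: list[str] | None = None


def master_scaffold() -> list[str]:
    global _SCAFFOLD_CACHE
    if _SCAFFOLD_CACHE is None:
        _SCAFFOLD_CACHE = _master_scaffold()
    return list(_SCAFFOLD_CACHE)


def _mutate_master(letters: list[str], divergence: float, rng) -> list[str]:
    """JTT-conditional mutation of mutable master columns."""
    p = default_model().transition_matrix(divergence)
    p = p / p.sum(axis=1, keepdims=True)
    out = list(letters)
    for c in range(len(out)):
        if c in _CONSERVED or c in _PLANTED_MASTER:
            continue
        a = _AA_INDEX[out[c]]
        out[c] = _AA[rng.choice(20, p=p[a])]
    return out


# ---------------------------------------------------------------------------
# Templates


_SUBFAMILY_DEFAULTS = {
    # subfamily: (box1, box2, filter H2/H5/LE1/LE2, cterm)
    "GIP": ("NPA", "NPA", "WVAR", "Q"),
    "PIP": ("NPA", "NPA", "FHAR", "Q"),
    "MIPE": ("NPA", "NPA", "FHCR", "Q"),
    "LIP": ("NPA", "NPM", "WLPL", "K"),
    "SIP": ("NPT", "NPA", "STAR", "K"),
    "MIPC": ("NPT", "NPA", "FVAR", "Q"),
    "bacterial": ("NPA", "NPA", "TASV", "Q"),
    "unclassified": ("NPA", "NPA", "FHCR", "Q"),
}


def _plant(letters_by_col: dict[int, str], box1: str, box2: str, filt: str, cols=None):
    for col, ch in zip(_BOX1_COLS, box1):
        letters_by_col[col] = ch
    for col, ch in zip(_BOX2_COLS, box2):
        letters_by_col[col] = ch
    for col, ch in zip(_F_COLS, filt):
        letters_by_col[col] = ch


def _panel_sequence_letters(
    master_letters: list[str],
    box1: str,
    box2: str,
    filt: str,
    cterm: str,
    length: int,
    rng,
) -> tuple[list[str], list[int]]:
    """Residues + occupied master columns for one panel-geometry sequence."""
    if not 225 <= length <= 340:
        raise ValueError(f"panel-geometry length {length} outside [225, 340]")
    by_col = {c: master_letters[c] for c in _PANEL_COLS}
    _plant(by_col, box1, box2, filt)
    cols = list(_PANEL_COLS)
    n_del = 340 - length
    if n_del:
        # drop a contiguous run after the LE2 flank, keeping the C terminus
        tail_start = _SEG_RANGES[4][0] + 5
        drop = set(range(tail_start, tail_start + n_del))
        cols = [c for c in cols if c not in drop]
    by_col[cols[-1]] = cterm
    letters = [by_col[c] for c in cols]
    immutable = {
        i
        for i, c in enumerate(cols)
        if c in _CONSERVED or c in _PLANTED_MASTER or i == len(cols) - 1
    }
    planted_n = {i for i, c in enumerate(cols) if c in (_BOX1_COLS[0], _BOX2_COLS[0])}
    _scrub_bigram(letters, immutable, rng, planted_n)
    return letters, cols


_TEMPLATE_ORDER = ("GIP", "PIP", "MIPE", "LIP", "bacterial", "unclassified")


def subfamily_templates() -> dict[str, MIPTemplate]:
    """Fixed length-340 templates, one per subfamily present in the panel.

    Each template is the master scaffold diverged by 0.35 expected
    substitutions per site at mutable columns, with the subfamily's
    canonical boxes and filter planted, so subfamily identity is encoded in
    both the diagnostic sites and the background divergence structure.
    """
    out = {}
    scaffold = master_scaffold()
    for k, label in enumerate(_TEMPLATE_ORDER):
        rng = np.random.default_rng([_TEMPLATE_SEED, k])
        mutated = _mutate_master(scaffold, 0.35, rng)
        box1, box2, filt, cterm = _SUBFAMILY_DEFAULTS[label]
        letters, cols = _panel_sequence_letters(mutated, box1, box2, filt, cterm, 340, rng)
        out[label] = MIPTemplate(
            template_id=f"TPL_{label}",
            residues="".join(letters),
            box1_start=PANEL_BOX1,
            box2_start=PANEL_BOX2,
            h2_pos=PANEL_H2,
            h5_pos=PANEL_H5,
            le1_pos=PANEL_LE1,
            le2_pos=PANEL_LE2,
            subfamily_label=label,
        )
    return out


def make_template(seed: int, subfamily_label: str = "unclassified", length: int = 340) -> MIPTemplate:
    """A fresh template with the panel geometry and a seeded background.

    Unlike :func:`subfamily_templates`, the background here is drawn
    independently of the master scaffold, so templates made with different
    seeds are unrelated (useful for simulating well-separated families).
    """
    rng = np.random.default_rng([int(seed), 77])
    letters = _draw_background(MASTER_LEN, rng)
    box1, box2, filt, cterm = _SUBFAMILY_DEFAULTS[subfamily_label]
    letters, cols = _panel_sequence_letters(letters, box1, box2, filt, cterm, length, rng)
    return MIPTemplate(
        template_id=f"T{seed}_{subfamily_label}",
        residues="".join(letters),
        box1_start=PANEL_BOX1,
        box2_start=PANEL_BOX2,
        h2_pos=PANEL_H2,
        h5_pos=PANEL_H5,
        le1_pos=PANEL_LE1,
        le2_pos=PANEL_LE2,
        subfamily_label=subfamily_label,
    )


def make_template_family(
    seed: int,
    n_templates: int,
    divergence: float = 0.45,
    subfamily_label: str = "unclassified",
) -> list[MIPTemplate]:
    """Related templates: descendants of one root template, without indels.

    Each template sits ``divergence`` expected substitutions per site from the
    common root, i.e. about twice that from its siblings — far above typical
    within-family divergence yet well below saturation, so distances between
    families remain statistically estimable. (Templates with unrelated random
    backgrounds would push pairwise distances into saturation, where
    neighbour joining placements of the long branches become unstable.)
    """
    root = make_template(seed, subfamily_label)
    seqs, _ = generate_family(
        root, n=n_templates, divergence=divergence, indel_rate=0.0, seed=seed * 7 + 1
    )
    return [
        MIPTemplate(
            template_id=f"T{seed}F{k}_{subfamily_label}",
            residues=s.residues,
            box1_start=root.box1_start,
            box2_start=root.box2_start,
            h2_pos=root.h2_pos,
            h5_pos=root.h5_pos,
            le1_pos=root.le1_pos,
            le2_pos=root.le2_pos,
            subfamily_label=subfamily_label,
        )
        for k, s in enumerate(seqs)
    ]


# ---------------------------------------------------------------------------
# Family simulation


def _protected_positions(template: MIPTemplate) -> tuple[frozenset[int], frozenset[int]]:
    """(substitution-protected, indel-protected) 0-based template positions."""
    subs = set()
    for s in (template.box1_start, template.box2_start):
        subs.update(range(s - 1, s + 2))
    for p in (template.h2_pos, template.h5_pos, template.le1_pos, template.le2_pos):
        subs.add(p - 1)
    subs.add(len(template.residues) - 1)
    indel = set()
    for s in (template.box1_start, template.box2_start):
        indel.update(range(s - 2, s + 3))  # box start-1 .. start+3, 1-based
    for p in (template.h2_pos, template.h5_pos, template.le1_pos, template.le2_pos):
        indel.update(range(p - 2, p + 1))  # filter position +-1, 1-based
    indel.add(len(template.residues) - 1)
    return frozenset(subs), frozenset(indel)


def uniform_expected_difference(divergence: float) -> float:
    """Expected differing-site proportion under the uniform 20-state process.

    With substitution events arriving as Poisson(d) per site and each event
    replacing the residue uniformly among the 19 alternatives, the chance a
    site ends up differing from the template is (19/20)(1 - exp(-20 d / 19)).
    """
    return 19.0 / 20.0 * (1.0 - np.exp(-20.0 * divergence / 19.0))


def generate_family(
    template: MIPTemplate,
    n: int,
    divergence: float,
    indel_rate: float = 0.005,
    seed: int = 0,
    substitution_model: str = "uniform",
) -> tuple[list[MIPSequence], list[SimTruth]]:
    """Simulate ``n`` descendants of ``template`` with planted truth.

    ``divergence`` is the expected number of substitutions per mutable site.
    Under the default uniform model each site receives Poisson(divergence)
    replacement events, each uniform over the 19 alternative residues; under
    ``substitution_model="jtt"`` the site's letter is redrawn from the JTT
    transition distribution at that divergence. ``indel_rate`` is the
    per-site probability of starting an indel (insertion or deletion with
    equal probability, geometric length with mean 2); indels that would
    touch a protected window are re-drawn elsewhere. Planted boxes, filter
    residues and the C-terminal residue never mutate.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= divergence < 1.0:
        raise ValueError("divergence must lie in [0, 1)")
    if indel_rate < 0:
        raise ValueError("indel_rate must be non-negative")
    if substitution_model not in ("uniform", "jtt"):
        raise ValueError(f"unknown substitution model {substitution_model!r}")

    subs_protected, indel_protected = _protected_positions(template)
    tmpl = template.residues
    model = default_model()
    p_jtt = None
    if substitution_model == "jtt" and divergence > 0:
        p_jtt = model.transition_matrix(divergence)
        p_jtt = p_jtt / p_jtt.sum(axis=1, keepdims=True)

    sequences, truths = [], []
    for k in range(n):
        rng = np.random.default_rng([int(seed), int(k)])
        letters = list(tmpl)
        if divergence > 0:
            for i in range(len(letters)):
                if i in subs_protected:
                    continue
                if p_jtt is not None:
                    letters[i] = _AA[rng.choice(20, p=p_jtt[_AA_INDEX[letters[i]]])]
                else:
                    hits = rng.poisson(divergence)
                    for _ in range(hits):
                        alt = [a for a in AMINO_ACIDS if a != letters[i]]
                        letters[i] = alt[rng.integers(19)]
        # items: (template column or None, letter), in sequence order
        items: list[tuple[int | None, str]] = list(enumerate(letters))
        if indel_rate > 0:
            items = _apply_indels(items, indel_rate, indel_protected, rng)
        seq_letters = [ch for _, ch in items]
        immutable = {i for i, (c, _) in enumerate(items) if c in subs_protected}
        planted_n = {
            i
            for i, (c, _) in enumerate(items)
            if c in (template.box1_start - 1, template.box2_start - 1)
        }
        _scrub_bigram(seq_letters, immutable, rng, planted_n)
        items = [(c, ch) for (c, _), ch in zip(items, seq_letters)]

        seq_id = f"{template.template_id}_{k:04d}"
        seq = "".join(ch for _, ch in items)
        pos_of_col = {c: i + 1 for i, (c, _) in enumerate(items) if c is not None}
        query_row, tmpl_row = _true_rows(items, tmpl)
        truths.append(
            SimTruth(
                seq_id=seq_id,
                source_template_id=template.template_id,
                planted_box1=template.box1,
                planted_box2=template.box2,
                planted_filter=template.filter_string,
                planted_cterm=tmpl[-1],
                true_alignment_row=query_row,
                true_template_row=tmpl_row,
                subfamily_label=template.subfamily_label,
                box1_start=pos_of_col[template.box1_start - 1],
                box2_start=pos_of_col[template.box2_start - 1],
                h2_pos=pos_of_col[template.h2_pos - 1],
                h5_pos=pos_of_col[template.h5_pos - 1],
                le1_pos=pos_of_col[template.le1_pos - 1],
                le2_pos=pos_of_col[template.le2_pos - 1],
            )
        )
        sequences.append(MIPSequence(seq_id=seq_id, residues=seq))
    return sequences, truths


def _apply_indels(items, indel_rate: float, indel_protected, rng):
    """Place indels between/over mutable sites; re-draw ones hitting
    protected windows (up to a bounded number of attempts each)."""
    pi = default_model().pi
    n_sites = len(items)
    events = []
    for i in range(n_sites):
        if rng.random() >= indel_rate:
            continue
        for _ in range(10):  # re-draw budget
            length = int(rng.geometric(0.5))
            is_del = rng.random() < 0.5
            if is_del:
                span = range(i, min(i + length, n_sites))
                if any(items[j][0] in indel_protected for j in span):
                    continue
                events.append(("del", i, length))
            else:
                # an insertion lands before site i; keep it out of protected
                # windows so planted boxes are never split
                if items[i][0] in indel_protected:
                    continue
                events.append(("ins", i, length))
            break
    deleted = set()
    insertions: dict[int, list[str]] = {}
    for kind, i, length in events:
        if kind == "del":
            deleted.update(range(i, min(i + length, n_sites)))
        else:
            insertions.setdefault(i, []).extend(
                _AA[rng.choice(20, size=length, p=pi / pi.sum())]
            )
    out = []
    for i, (col, ch) in enumerate(items):
        if i in insertions:
            out.extend((None, c) for c in insertions[i])
        if i not in deleted:
            out.append((col, ch))
    return out


def _true_rows(items, tmpl: str) -> tuple[str, str]:
    """Build the true pairwise alignment (gapped query, gapped template)."""
    q, t = [], []
    next_col = 0
    for col, ch in items:
        if col is None:
            q.append(ch)
            t.append(GAP)
            continue
        while next_col < col:  # deleted template columns
            q.append(GAP)
            t.append(tmpl[next_col])
            next_col += 1
        q.append(ch)
        t.append(tmpl[col])
        next_col = col + 1
    while next_col < len(tmpl):
        q.append(GAP)
        t.append(tmpl[next_col])
        next_col += 1
    return "".join(q), "".join(t)


# ---------------------------------------------------------------------------
# Packaged synthetic references


def packaged_references() -> list[ReferenceAnnotation]:
    """The two packaged reference annotations, HsAQP1-like then EcGlpF-like.

    Synthetic stand-ins: background residues are generated, but each carries
    the published ar/R filter letters at the published 1-based positions
    (HsAQP1: F56, H180, C189, R195; EcGlpF: W48, G191, F200, R205) and NPA
    boxes in MIP-like placement, and each occupies known columns of the
    master alignment so panel sequences align to it meaningfully.
    """
    scaffold = master_scaffold()
    refs = []
    for k, (name, cols, positions, filt, desc) in enumerate(
        (
            ("HsAQP1", _HS_COLS, (56, 180, 189, 195), "FHCR", "synthetic aquaporin-like reference"),
            ("EcGlpF", _EC_COLS, (48, 191, 200, 205), "WGFR", "synthetic glyceroporin-like reference"),
        )
    ):
        rng = np.random.default_rng([_REFERENCE_SEED, k])
        mutated = _mutate_master(scaffold, 0.3, rng)
        by_col = {c: mutated[c] for c in cols}
        _plant(by_col, "NPA", "NPA", filt)
        letters = [by_col[c] for c in cols]
        immutable = {
            i for i, c in enumerate(cols) if c in _CONSERVED or c in _PLANTED_MASTER
        }
        planted_n = {i for i, c in enumerate(cols) if c in (_BOX1_COLS[0], _BOX2_COLS[0])}
        _scrub_bigram(letters, immutable, rng, planted_n)
        ref = ReferenceAnnotation(
            ref_id=name,
            residues="".join(letters),
            h2_pos=positions[0],
            h5_pos=positions[1],
            le1_pos=positions[2],
            le2_pos=positions[3],
            description=desc,
        )
        if ref.filter_string != filt:
            raise AssertionError(
                f"reference {name} filter {ref.filter_string} != published {filt}"
            )
        refs.append(ref)
    return refs


def reference_msa_rows() -> dict[str, str]:
    """Master-alignment rows of the packaged references."""
    rows = {}
    for ref, cols in zip(packaged_references(), (_HS_COLS, _EC_COLS)):
        row = [GAP] * MASTER_LEN
        for ch, c in zip(ref.residues, cols):
            row[c] = ch
        rows[ref.ref_id] = "".join(row)
    return rows


# ---------------------------------------------------------------------------
# The heterokont panel

# (organism, subfamily, box1, box2, filter, cterm, length) per protein
_PANEL_SPEC = {
    "TpMIP1": ("Thalassiosira pseudonana", "bacterial", "NPA", "NPA", "IAGV", None, 250),
    "TpMIP2": ("Thalassiosira pseudonana", "LIP", "NPA", "NPM", "WIPL", "K", 305),
    "ToMIP1": ("Thalassiosira oceanica", "LIP", "NPA", "NPM", "WLPL", "K", 310),
    "ToMIP2": ("Thalassiosira oceanica", "bacterial", "NPA", "NPA", "IAGV", None, 252),
    "PtMIP1": ("Phaeodactylum tricornutum", "GIP", "NPA", "NPA", "WVAR", None, 260),
    "PtMIP2": ("Phaeodactylum tricornutum", "GIP", "NPA", "NPA", "WVGR", None, 262),
    "PtMIP3": ("Phaeodactylum tricornutum", "GIP", "NPA", "NPA", "WVAR", None, 264),
    "PtMIP4": ("Phaeodactylum tricornutum", "unclassified", "NPG", "NPA", "FHCR", None, 266),
    "PtMIP5": ("Phaeodactylum tricornutum", "LIP", "NPA", "NPM", "WLPL", "K", 300),
    "NgMIP": ("Nannochloropsis gaditana", "LIP", "NPA", "NPM", "WLPI", "K", 230),
    "SarMIP": ("Synedra acus subsp. radians", "LIP", "NPA", "NPM", "WLPL", "K", 286),
    "PnmMIP": ("Pseudo-nitzschia multiseries", "LIP", "NPA", "NPM", "WLPL", "K", 295),
    "FcMIP": ("Fragilariopsis cylindrus", "LIP", "NPA", "NPM", "WLPL", "K", 290),
    "EsAQP": ("Ectocarpus siliculosus", "PIP", "NPA", "NPA", "FHAR", None, 296),
    "EsPIP": ("Ectocarpus siliculosus", "PIP", "NPA", "NPA", "FHCR", None, 298),
    "EsMIP": ("Ectocarpus siliculosus", "LIP", "NPA", "NPM", "WLPI", "K", 225),
    "AaMIP1": ("Aureococcus anophagefferens", "LIP", "NPA", "NPA", "YVPL", None, 282),
    "AaMIP2": ("Aureococcus anophagefferens", "GIP", "NPA", "NPA", "FICR", None, 268),
    "AaMIP3": ("Aureococcus anophagefferens", "bacterial", "NPA", "NPA", "TASV", None, 254),
    "AaMIP4": ("Aureococcus anophagefferens", "MIPE", "NGA", "NPA", "FHCR", None, 258),
}

PANEL_IDS = tuple(_PANEL_SPEC)

#: labeled reference leaves included in the panel alignment for tree-based
#: subfamily assignment (two per assignable non-LIP subfamily)
_TREE_REF_GROUPS = ("GIP", "PIP", "MIPE")


@dataclass(frozen=True)
class HeterokontPanel:
    """The fixed 20-protein panel with planted truth and its true alignment.

    ``msa`` contains the 20 panel rows plus labeled reference leaves
    (``reference_labels``) over the master-alignment columns.
    """

    sequences: tuple[MIPSequence, ...]
    truth: dict[str, SimTruth]
    msa: Msa
    reference_labels: dict[str, str]


def generate_heterokont_panel(seed: int = 0) -> HeterokontPanel:
    """Generate the 20-protein heterokont panel.

    Planted NPA-box variants, ar/R filters, C-terminal residues and lengths
    encode the published description of these proteins; backgrounds derive
    from the fixed subfamily templates with 0.1 expected substitutions per
    mutable site of member-specific divergence, seeded by ``seed``.
    """
    templates = subfamily_templates()
    scaffold = master_scaffold()
    tmpl_master: dict[str, list[str]] = {}
    for k, label in enumerate(_TEMPLATE_ORDER):
        rng = np.random.default_rng([_TEMPLATE_SEED, k])
        tmpl_master[label] = _mutate_master(scaffold, 0.35, rng)

    sequences = []
    truth = {}
    msa_ids, msa_rows = [], []
    cterm_fallback = "ARDEQSTVLIFM"  # non-K letters for unspecified C termini
    for idx, (seq_id, spec) in enumerate(_PANEL_SPEC.items()):
        organism, label, box1, box2, filt, cterm, length = spec
        rng = np.random.default_rng([int(seed), 11, idx])
        member = _mutate_master(tmpl_master[label], 0.1, rng)
        if cterm is None:
            cterm = cterm_fallback[rng.integers(len(cterm_fallback))]
        letters, cols = _panel_sequence_letters(member, box1, box2, filt, cterm, length, rng)
        residues = "".join(letters)
        seq = MIPSequence(seq_id=seq_id, residues=residues, organism=organism)
        row = [GAP] * MASTER_LEN
        for ch, c in zip(letters, cols):
            row[c] = ch
        tmpl = templates[label]
        query_row = "".join(row)
        rank = {c: i for i, c in enumerate(_PANEL_COLS)}
        tmpl_row = "".join(
            tmpl.residues[rank[c]] if c in rank else GAP for c in range(MASTER_LEN)
        )
        truth[seq_id] = SimTruth(
            seq_id=seq_id,
            source_template_id=tmpl.template_id,
            planted_box1=box1,
            planted_box2=box2,
            planted_filter=filt,
            planted_cterm=cterm,
            true_alignment_row=query_row,
            true_template_row=tmpl_row,
            subfamily_label=label,
            box1_start=PANEL_BOX1,
            box2_start=PANEL_BOX2,
            h2_pos=PANEL_H2,
            h5_pos=PANEL_H5,
            le1_pos=PANEL_LE1,
            le2_pos=PANEL_LE2,
        )
        sequences.append(seq)
        msa_ids.append(seq_id)
        msa_rows.append(query_row)

    reference_labels = {}
    for g, label in enumerate(_TREE_REF_GROUPS):
        for j in (1, 2):
            rng = np.random.default_rng([int(seed), 23, g, j])
            member = _mutate_master(tmpl_master[label], 0.1, rng)
            box1, box2, filt, cterm = _SUBFAMILY_DEFAULTS[label]
            letters, cols = _panel_sequence_letters(member, box1, box2, filt, cterm, 340, rng)
            ref_id = f"REF_{label}{j}"
            row = [GAP] * MASTER_LEN
            for ch, c in zip(letters, cols):
                row[c] = ch
            msa_ids.append(ref_id)
            msa_rows.append("".join(row))
            reference_labels[ref_id] = label

    msa = Msa(tuple(msa_ids), tuple(msa_rows))
    return HeterokontPanel(
        sequences=tuple(sequences),
        truth=truth,
        msa=msa,
        reference_labels=reference_labels,
    )


# ---------------------------------------------------------------------------
# Truth-table I/O

_TRUTH_FIELDS = (
    "seq_id",
    "source_template_id",
    "subfamily_label",
    "planted_box1",
    "planted_box2",
    "planted_filter",
    "planted_cterm",
    "box1_start",
    "box2_start",
    "h2_pos",
    "h5_pos",
    "le1_pos",
    "le2_pos",
    "true_alignment_row",
    "true_template_row",
)


def write_truth_tables(
    sequences, truths, fasta_path, truth_path
) -> None:
    """Write sequences as FASTA and their planted truth as a TSV table."""
    truths = list(truths.values()) if isinstance(truths, dict) else list(truths)
    fasta_path, truth_path = Path(fasta_path), Path(truth_path)
    try:
        write_fasta(sequences, fasta_path)
        with open(truth_path, "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=_TRUTH_FIELDS, delimiter="\t")
            w.writeheader()
            for t in truths:
                w.writerow({f: getattr(t, f) for f in _TRUTH_FIELDS})
    except OSError as exc:
        raise OSError(f"failed writing truth tables ({exc.filename}): {exc}") from exc


def read_truth_table(truth_path) -> list[SimTruth]:
    with open(truth_path, newline="") as fh:
        rows = list(csv.DictReader(fh, delimiter="\t"))
    out = []
    for r in rows:
        kwargs = dict(r)
        for f in ("box1_start", "box2_start", "h2_pos", "h5_pos", "le1_pos", "le2_pos"):
            kwargs[f] = int(kwargs[f])
        out.append(SimTruth(**kwargs))
    return out


def write_fasta(sequences, path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(s.residues), id=s.seq_id, description=s.organism) for s in sequences
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> list[MIPSequence]:
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description[len(rec.id) :].strip() if rec.description else ""
        out.append(MIPSequence(seq_id=rec.id, residues=str(rec.seq).upper(), organism=desc))
    return out
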