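"""Subfamily assignment from motif, filter, terminal-residue and tree evidence.

The LIP ("large intrinsic protein") subfamily is delineated first and purely
from the ar/R filter: proline at LE1 together with leucine or isoleucine at
LE2 is the primary criterion; an NPM second box, a C-terminal lysine and
W/Y at H2 are corroborating features. Tree placement next to labeled
reference groups resolves the remaining subfamilies (GIP, PIP, MIPE), with
filter composition rules as a tree-free fallback. PIP and MIPE cannot be
separated by filter alone (both match the aquaporin water rule), so without
informative tree evidence such calls stay unclassified with both candidates
recorded.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass

from .arfilter import infer_specificity
from .phylo import PhyloTree
from .records import ArRFilter, LipSignature, NpaBoxPair, SubfamilyCall

DEFAULT_SUPPORT_THRESHOLD = 50.0


def lip_signature(filt: ArRFilter, boxes: NpaBoxPair, cterm: str) -> LipSignature:
    """The five LIP diagnostic booleans, computed literally.

    Filter roles holding a gap evaluate false for their features.
    """
    return LipSignature(
        le1_is_P=filt.le1 == "P",
        le2_in_LI=filt.le2 in ("L", "I"),
        second_box_NPM=boxes.second is not None and boxes.second.motif == "NPM",
        cterm_K=cterm == "K",
        h2_in_WY=filt.h2 in ("W", "Y"),
    )


@dataclass(frozen=True)
class EvidenceBundle:
    """Everything known about one query before subfamily assignment."""

    seq_id: str
    filt: ArRFilter
    boxes: NpaBoxPair
    cterm: str


def _tree_group(
    seq_id: str,
    tree: PhyloTree,
    reference_labels: dict[str, str],
    support_threshold: float,
) -> tuple[str | None, float | None]:
    """The reference group the query clusters with, if unambiguous.

    The smallest tree bipartition containing the query together with every
    reference leaf of a group qualifies when it contains no reference leaf
    of any other group and its edge support meets the threshold.
    """
    leaves = tree.leaf_names
    known = {"PIP", "GIP", "MIPE", "LIP"}
    bad = set(reference_labels.values()) - known
    if bad:
        raise ValueError(f"unknown reference label(s): {sorted(bad)}")
    if seq_id not in leaves:
        return None, None
    groups: dict[str, set[str]] = {}
    for leaf, label in reference_labels.items():
        if leaf in leaves:
            groups.setdefault(label, set()).add(leaf)
    bips = tree.bipartitions()
    all_refs = {l for s in groups.values() for l in s}
    best: tuple[str, float | None, int] | None = None
    ambiguous = False
    for label, members in groups.items():
        want = members | {seq_id}
        containing = []
        for side, node in bips.items():
            if want <= side:
                containing.append((len(side), side, node))
            if want <= (leaves - side):
                containing.append((len(leaves - side), leaves - side, node))
        # smallest clade holding the query and the whole group that contains
        # no other group's references and whose edge support is adequate
        qualifying = None
        for size, side, node in sorted(containing, key=lambda t: t[0]):
            if (all_refs - members) & side:
                continue
            if node.support is not None and node.support < support_threshold:
                continue
            qualifying = (label, node.support, size)
            break
        if qualifying is None:
            continue
        if best is None or qualifying[2] < best[2]:
            best = qualifying
            ambiguous = False
        elif qualifying[2] == best[2]:
            ambiguous = True
    if best is None or ambiguous:
        return None, None
    return best[0], best[1]


def assign_subfamily(
    bundle: EvidenceBundle,
    tree: PhyloTree | None = None,
    reference_labels: dict[str, str] | None = None,
    support_threshold: float = DEFAULT_SUPPORT_THRESHOLD,
) -> SubfamilyCall:
    """Assign a subfamily with a full evidence trail.

    Precedence: (1) the LIP filter signature (tree-independent, so a LIP
    call never changes when the tree is withheld); (2) unambiguous tree
    placement with a labeled reference group at adequate support; (3) the
    glycerol-permease filter rule -> GIP; (4) the water filter rule -> PIP
    or MIPE, resolved only by tree evidence; (5) unclassified. A tree
    placement that contradicts the LIP signature is logged as a conflict,
    with the signature winning.
    """
    filt, boxes = bundle.filt, bundle.boxes
    spec = infer_specificity(filt)
    sig = lip_signature(filt, boxes, bundle.cterm)
    evidence: list[tuple[str, str]] = [
        ("filter", filt.filter_string),
        ("boxes", f"{boxes.first.motif if boxes.first else '-'}/"
                  f"{boxes.second.motif if boxes.second else '-'}"),
        ("cterm", bundle.cterm),
        ("specificity_rule", spec.rule_id),
    ]
    placement, support = (None, None)
    if tree is not None and reference_labels:
        placement, support = _tree_group(
            bundle.seq_id, tree, reference_labels, support_threshold
        )
        if placement is not None:
            evidence.append(("tree_placement", f"{placement}@{support if support is not None else 'NA'}"))

    if sig.primary:
        evidence.append(
            (
                "lip_filter_signature",
                f"LE1=P:{sig.le1_is_P} LE2 in LI:{sig.le2_in_LI} "
                f"NPM2:{sig.second_box_NPM} ctermK:{sig.cterm_K} H2 in WY:{sig.h2_in_WY}",
            )
        )
        if placement is not None and placement != "LIP":
            evidence.append(("conflict", f"tree placed with {placement}; LIP signature wins"))
        return SubfamilyCall(
            seq_id=bundle.seq_id,
            subfamily="LIP",
            specificity=spec,
            evidence=tuple(evidence),
            clade_support=support if placement == "LIP" else None,
        )

    if placement is not None:
        return SubfamilyCall(
            seq_id=bundle.seq_id,
            subfamily=placement,
            specificity=spec,
            evidence=tuple(evidence),
            clade_support=support,
        )

    if spec.rule_id == "G":
        evidence.append(("filter_rule_G", "glyceroporin composition W-V-[A/G]-R"))
        return SubfamilyCall(
            seq_id=bundle.seq_id, subfamily="GIP", specificity=spec, evidence=tuple(evidence)
        )

    if spec.rule_id == "W":
        evidence.append(("filter_rule_W", "aquaporin composition F-H-[A/C]-R"))
        evidence.append(("candidates", "PIP|MIPE (filter cannot separate; no tree support)"))
        return SubfamilyCall(
            seq_id=bundle.seq_id,
            subfamily="unclassified",
            specificity=spec,
            evidence=tuple(evidence),
        )

    evidence.append(("no_rule", "no filter rule fired and no informative tree placement"))
    return SubfamilyCall(
        seq_id=bundle.seq_id, subfamily="unclassified", specificity=spec, evidence=tuple(evidence)
    )


def summarize_calls(calls: list[SubfamilyCall]) -> dict:
    """Counts per subfamily and per specificity, in stable order."""
    if not calls:
        raise ValueError("no calls to summarize")
    sub = Counter(c.subfamily for c in calls)
    spec = Counter(c.specificity.specificity for c in calls)
    order_sub = ("PIP", "GIP", "MIPE", "LIP", "unclassified")
    order_spec = ("water", "glycerol permease", "unknown")
    return {
        "n": len(calls),
        "subfamily_counts": {k: sub.get(k, 0) for k in order_sub},
        "specificity_counts": {k: spec.get(k, 0) for k in order_spec},
        "members": {
            k: sorted(c.seq_id for c in calls if c.subfamily == k) for k in order_sub
        },
    }


def write_calls_tsv(calls, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "seq_id\tsubfamily\tfilter\tspecificity\trule_id\tclade_support\tevidence\n"
        )
        for c in calls:
            ev = ";".join(f"{r}={d}" for r, d in c.evidence)
            support = "" if c.clade_support is None else f"{c.clade_support:.1f}"
            fh.write(
                f"{c.seq_id}\t{c.subfamily}\t{c.specificity.filter_string}\t"
                f"{c.specificity.specificity}\t{c.specificity.rule_id}\t{support}\t{ev}\n"
            )


def write_summary_json(summary: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
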