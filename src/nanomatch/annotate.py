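"""Framework/CDR annotation of VHH proteins by conserved anchor motifs.

Immunoglobulin variable domains carry four highly conserved landmarks
that bracket the hypervariable loops: the first cysteine (IMGT 23, in
FR1), the tryptophan following CDR1 (IMGT 41), the second cysteine
preceding CDR3 (IMGT 104, typically in a Y-x-C context at the end of
FR3), and the FR4 W-G-x-G motif whose tryptophan is IMGT 118. This
module locates those anchors in configurable windows, derives FR1-FR4 /
CDR1-3 boundaries from them, pins an IMGT-style position map to the
anchors, and flags the VH-hallmark GLEW tetrad at IMGT 49-52 (a marker
of conventional-VH contamination in a VHH database).

This is a lightweight, anchor-pinned approximation of full
profile-HMM-based numbering; externally computed numberings can be
imported instead via :func:`import_external_numbering`.
"""

from __future__ import annotations

import dataclasses
import enum
import logging
from typing import Optional, Sequence

logger = logging.getLogger("nanomatch")

REGIONS = ("FR1", "CDR1", "FR2", "CDR2", "FR3", "CDR3", "FR4")

#: IMGT region bounds (inclusive) used when rebuilding annotations from an
#: imported numbering table.
IMGT_REGION_BOUNDS = {
    "FR1": (1, 26),
    "CDR1": (27, 38),
    "FR2": (39, 55),
    "CDR2": (56, 65),
    "FR3": (66, 104),
    "CDR3": (105, 117),
    "FR4": (118, 128),
}

# Anchor IMGT positions.
IMGT_CYS1 = 23
IMGT_TRP41 = 41
IMGT_CYS2 = 104
IMGT_FR4_TRP = 118


class Confidence(str, enum.Enum):
    FULL = "full"
    PARTIAL = "partial"
    FAILED = "failed"


@dataclasses.dataclass(frozen=True)
class AnchorSpec:
    """One boundary anchor: candidate patterns (``x`` = wildcard), the
    index within the pattern that is the anchor residue, and the window
    of candidate anchor positions (0-based, inclusive)."""

    patterns: tuple[str, ...]
    anchor_index: int
    window: tuple[int, int]

    def __post_init__(self):
        if not self.patterns:
            raise ValueError("anchor needs at least one pattern")


@dataclasses.dataclass(frozen=True)
class AnchorConfig:
    """Anchor motifs for the four framework landmarks.

    Defaults cover the canonical immunoglobulin anchors with windows
    wide enough for CDR1 lengths 5-12 and CDR2 lengths 4-10; every
    field is overridable for unusual repertoires. The FR4 window is
    relative to the end of the sequence (last ``fr4_tail`` residues).
    """

    cys1: AnchorSpec = AnchorSpec(patterns=("C",), anchor_index=0, window=(18, 30))
    trp41: AnchorSpec = AnchorSpec(patterns=("W",), anchor_index=0, window=(31, 48))
    cys2: AnchorSpec = AnchorSpec(patterns=("YxC", "C"), anchor_index=-1, window=(85, 112))
    fr4: AnchorSpec = AnchorSpec(patterns=("WGxG",), anchor_index=0, window=(0, 0))
    fr4_tail: int = 15


DEFAULT_ANCHOR_CONFIG = AnchorConfig()


@dataclasses.dataclass(frozen=True)
class CdrAnnotation:
    """Region boundaries (0-based, half-open) plus an IMGT position map.

    Unresolved regions are ``None``; ``imgt_map`` maps residue index to
    an IMGT position (float: insertion codes appear as fractional
    positions, e.g. 111.1) and is strictly monotone increasing.
    """

    regions: dict[str, Optional[tuple[int, int]]]
    imgt_map: dict[int, float]
    confidence: Confidence
    anchors: dict[str, Optional[int]] = dataclasses.field(default_factory=dict)

    def region(self, name: str) -> Optional[tuple[int, int]]:
        return self.regions.get(name)

    def cdr3_span(self) -> Optional[tuple[int, int]]:
        return self.regions.get("CDR3")

    def cdr3(self, protein: str) -> Optional[str]:
        span = self.cdr3_span()
        if span is None:
            return None
        return protein[span[0]:span[1]]

    def residue_at_imgt(self, protein: str, imgt_pos: float) -> Optional[str]:
        for idx, pos in self.imgt_map.items():
            if pos == imgt_pos:
                return protein[idx]
        return None


def _match_anchor(protein: str, spec: AnchorSpec, window: tuple[int, int]) -> Optional[int]:
    """Best anchor position: exact pattern match preferred (first pattern
    first), then single-mismatch matches of patterns of length >= 3,
    leftmost wins. Returns the anchor residue index or None."""
    lo, hi = window
    for max_mism in (0, 1):
        for pattern in spec.patterns:
            if max_mism > 0 and len(pattern) < 3:
                continue
            aidx = spec.anchor_index % len(pattern)
            for anchor_pos in range(max(lo, 0), min(hi, len(protein) - 1) + 1):
                start = anchor_pos - aidx
                end = start + len(pattern)
                if start < 0 or end > len(protein):
                    continue
                mism = sum(
                    1
                    for p, r in zip(pattern, protein[start:end])
                    if p != "x" and p != r
                )
                # the anchor residue itself must always match exactly
                if protein[anchor_pos] != pattern[aidx]:
                    continue
                if mism <= max_mism:
                    return anchor_pos
    return None


def annotate_regions(protein: str, cfg: AnchorConfig = DEFAULT_ANCHOR_CONFIG) -> CdrAnnotation:
    """Locate the four anchors and derive FR/CDR boundaries.

    Failed anchors degrade ``confidence`` and leave dependent regions
    unresolved (``None``) rather than guessed: downstream scoring gives
    unresolved regions zero weight. Confidence is ``full`` when all four
    anchors resolve in consistent order, ``partial`` when at least two
    do, else ``failed``.
    """
    n = len(protein)
    cys1 = _match_anchor(protein, cfg.cys1, cfg.cys1.window)
    trp = _match_anchor(protein, cfg.trp41, cfg.trp41.window)
    cys2 = _match_anchor(protein, cfg.cys2, cfg.cys2.window)
    fr4_window = (max(0, n - cfg.fr4_tail), n - 1)
    fr4 = _match_anchor(protein, cfg.fr4, fr4_window)

    anchors = {"cys1": cys1, "trp41": trp, "cys2": cys2, "fr4": fr4}
    # enforce ordering: drop later anchors that contradict earlier ones
    ordered = [a for a in (cys1, trp, cys2, fr4) if a is not None]
    if ordered != sorted(ordered) or len(set(ordered)) != len(ordered):
        # inconsistent layout: keep nothing rather than guess
        anchors = {k: None for k in anchors}
        cys1 = trp = cys2 = fr4 = None

    regions: dict[str, Optional[tuple[int, int]]] = {r: None for r in REGIONS}
    if cys1 is not None:
        regions["FR1"] = (0, min(cys1 + 4, n))
    if cys1 is not None and trp is not None and cys1 + 4 <= trp - 2:
        regions["CDR1"] = (cys1 + 4, trp - 2)
    if trp is not None:
        fr2_end = trp + 15
        if cys2 is not None:
            fr2_end = min(fr2_end, cys2)
        regions["FR2"] = (trp - 2, fr2_end)
    if trp is not None and cys2 is not None and trp + 15 <= cys2 - 38:
        regions["CDR2"] = (trp + 15, cys2 - 38)
        regions["FR3"] = (cys2 - 38, cys2 + 1)
    elif cys2 is not None:
        # CDR2 could not be resolved; FR3 still pinned back from the Cys
        regions["FR3"] = (max(0, cys2 - 38), cys2 + 1)
    if cys2 is not None and fr4 is not None and cys2 + 1 <= fr4:
        regions["CDR3"] = (cys2 + 1, fr4)
    if fr4 is not None:
        regions["FR4"] = (fr4, n)

    n_resolved = sum(a is not None for a in anchors.values())
    if n_resolved == 4 and all(regions[r] is not None for r in REGIONS):
        confidence = Confidence.FULL
    elif n_resolved >= 2:
        confidence = Confidence.PARTIAL
    else:
        confidence = Confidence.FAILED

    imgt_map = _build_imgt_map(protein, regions, anchors) if confidence != Confidence.FAILED else {}
    return CdrAnnotation(regions=regions, imgt_map=imgt_map, confidence=confidence, anchors=anchors)


def _loop_positions(length: int, lo: int, hi: int) -> list[float]:
    """IMGT-style numbering for a variable-length loop occupying slots
    ``lo..hi`` (inclusive). Residues fill from both ends toward the
    middle (gap in the middle for short loops; for odd lengths the extra
    residue sits N-terminal). Loops longer than the slot count receive
    fractional insertion codes ascending from the middle slot, keeping
    the map numerically monotone."""
    slots = hi - lo + 1
    if length <= slots:
        n_front = (length + 1) // 2
        n_back = length - n_front
        front = [lo + i for i in range(n_front)]
        back = [hi - n_back + 1 + i for i in range(n_back)]
        return [float(p) for p in front + back]
    mid = lo + (slots + 1) // 2 - 1  # e.g. 111 for CDR3 slots 105-117
    extra = length - slots
    front = [float(p) for p in range(lo, mid + 1)]
    inserts = [mid + 0.001 * (i + 1) for i in range(extra)]
    back = [float(p) for p in range(mid + 1, hi + 1)]
    return front + inserts + back


def _build_imgt_map(protein, regions, anchors) -> dict[int, float]:
    imgt: dict[int, float] = {}
    cys1, trp, cys2, fr4 = anchors.get("cys1"), anchors.get("trp41"), anchors.get("cys2"), anchors.get("fr4")
    if cys1 is not None and regions.get("FR1"):
        s, e = regions["FR1"]
        for i in range(s, e):
            pos = IMGT_CYS1 + (i - cys1)
            if pos >= 1:
                imgt[i] = float(pos)
    if trp is not None and regions.get("FR2"):
        s, e = regions["FR2"]
        for i in range(s, e):
            imgt[i] = float(IMGT_TRP41 + (i - trp))
    if cys2 is not None and regions.get("FR3"):
        s, e = regions["FR3"]
        for i in range(s, e):
            imgt[i] = float(IMGT_CYS2 - (cys2 - i))
    if fr4 is not None and regions.get("FR4"):
        s, e = regions["FR4"]
        for i in range(s, e):
            imgt[i] = float(IMGT_FR4_TRP + (i - fr4))
    for loop, (lo, hi) in (("CDR1", (27, 38)), ("CDR2", (56, 65)), ("CDR3", (105, 117))):
        span = regions.get(loop)
        if span is None:
            continue
        s, e = span
        for i, pos in zip(range(s, e), _loop_positions(e - s, lo, hi)):
            imgt[i] = pos
    # drop any position that breaks monotonicity (defensive; should not occur)
    out: dict[int, float] = {}
    last = 0.0
    for i in sorted(imgt):
        if imgt[i] > last:
            out[i] = imgt[i]
            last = imgt[i]
    return out


def imgt_positions(protein: str, annotation: CdrAnnotation) -> dict[int, float]:
    """The anchor-pinned IMGT position map for an annotated protein."""
    if annotation.confidence == Confidence.FAILED:
        raise ValueError(
            "annotation failed; import an external numbering via "
            "import_external_numbering instead"
        )
    return dict(annotation.imgt_map)


def has_vh_hallmark(protein: str, imgt_map: dict[int, float]) -> Optional[bool]:
    """True iff residues at IMGT 49-52 are exactly G, L, E, W.

    Conventional VH domains carry this hallmark; camelid VHH carry
    substitutions there, so a GLEW match marks a likely VH contaminant.
    Returns None (indeterminate, logged) when any of 49-52 is unmapped —
    an unannotatable sequence is not thereby a known contaminant.
    """
    inverse = {pos: idx for idx, pos in imgt_map.items()}
    try:
        residues = "".join(protein[inverse[float(p)]] for p in (49, 50, 51, 52))
    except KeyError:
        logger.info("GLEW check indeterminate: IMGT 49-52 not fully mapped")
        return None
    return residues == "GLEW"


def import_external_numbering(
    protein: str, numbering_table: Sequence[tuple[int, float]]
) -> CdrAnnotation:
    """Rebuild an annotation from an externally computed IMGT numbering.

    ``numbering_table`` rows are (residue index, IMGT position), strictly
    monotone in both columns. CDR boundaries follow the IMGT region
    definitions (CDR1 27-38, CDR2 56-65, CDR3 105-117).
    """
    if not numbering_table:
        raise ValueError("empty numbering table")
    idxs = [int(i) for i, _ in numbering_table]
    poss = [float(p) for _, p in numbering_table]
    if idxs != sorted(set(idxs)) or poss != sorted(set(poss)):
        raise ValueError("numbering table must be strictly monotone in both columns")
    if idxs[-1] >= len(protein):
        raise ValueError("numbering table indexes beyond the protein")
    imgt_map = dict(zip(idxs, poss))

    regions: dict[str, Optional[tuple[int, int]]] = {r: None for r in REGIONS}
    for name, (lo, hi) in IMGT_REGION_BOUNDS.items():
        if name == "FR4":
            hi = float("inf")  # the C-terminal tail (hinge stub) rides with FR4
        members = [i for i, p in imgt_map.items() if lo <= p < hi + 1]
        if members:
            regions[name] = (min(members), max(members) + 1)
    anchors = {}
    inverse = {p: i for i, p in imgt_map.items()}
    anchors["cys1"] = inverse.get(float(IMGT_CYS1))
    anchors["trp41"] = inverse.get(float(IMGT_TRP41))
    anchors["cys2"] = inverse.get(float(IMGT_CYS2))
    anchors["fr4"] = inverse.get(float(IMGT_FR4_TRP))
    n_regions = sum(r is not None for r in regions.values())
    confidence = Confidence.FULL if n_regions == len(REGIONS) else Confidence.PARTIAL
    return CdrAnnotation(regions=regions, imgt_map=imgt_map, confidence=confidence, anchors=anchors)
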