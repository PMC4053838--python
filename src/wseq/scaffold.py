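"""Z-gametologue-guided reconstruction of fragmented W transcripts.

W transcript pieces recovered from annotation, genome-guided assembly and
de-novo assembly are scattered over unplaced pseudo-chromosomes, so ordinary
genomic coordinates cannot order them.  W/Z gametologue pairs are largely
collinear and ~90% identical at the cDNA level, which makes the Z cDNA a
usable scaffold: each fragment is placed on it by alignment, ordered and
oriented, merged through sequence overlaps into consensus contigs, and the
remaining gaps are bridged with N-runs sized by the Z-scaffold distance.

Coordinates: scaffold coordinates are those of the Z cDNA, 0-based
half-open; consensus coordinates likewise.  Reports render 1-based
inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import edlib
import numpy as np

from .core import FRAGMENT_SOURCES, Fragment, check_dna, revcomp
from .discovery import OrfHit, find_orfs

__all__ = [
    "Placement",
    "ScaffoldLayout",
    "Contig",
    "MergedTranscript",
    "place_fragments",
    "merge_overlaps",
    "bridge_gaps",
    "assemble_w_transcript",
]

#: lower source index = higher priority in consensus tie-breaks
_SOURCE_PRIORITY = {s: i for i, s in enumerate(FRAGMENT_SOURCES)}


@dataclass
class Placement:
    fragment_id: str
    orientation: str          # '+' or '-'
    scaffold_start: int
    scaffold_end: int         # 0-based half-open on the Z cDNA
    identity: float           # fraction in [0, 1]
    sequence: str             # fragment sequence in scaffold (+) orientation
    source: str


@dataclass
class ScaffoldLayout:
    scaffold_length: int
    placements: list[Placement]        # sorted by scaffold_start
    unplaced: list[str] = field(default_factory=list)


@dataclass
class Contig:
    sequence: str
    scaffold_start: int
    scaffold_end: int
    depth: np.ndarray                  # per-base support
    provenance: list = field(default_factory=list)  # (start, end, frag_id, source)


@dataclass
class MergedTranscript:
    """Consensus contigs on the scaffold, optionally joined by N-bridges.

    ``bridges[i]`` is the N-run length between contig i and i+1 (None until
    :func:`bridge_gaps` runs, and None afterwards for unjoinable conflicts).
    ``sequence`` is the longest joined piece; ``completeness`` the fraction
    of the Z ORF covered by non-N consensus.
    """

    contigs: list[Contig] = field(default_factory=list)
    bridges: list = field(default_factory=list)
    conflicts: list = field(default_factory=list)
    completeness: float = 0.0
    bridged_intervals: list = field(default_factory=list)  # on `sequence`

    @property
    def pieces(self) -> list[str]:
        """Joined sequences: contigs concatenated through known N-bridges."""
        if not self.contigs:
            return []
        out, cur = [], self.contigs[0].sequence
        for i, contig in enumerate(self.contigs[1:]):
            gap = self.bridges[i] if i < len(self.bridges) else None
            if gap is None:
                out.append(cur)
                cur = contig.sequence
            else:
                cur += "N" * gap + contig.sequence
        out.append(cur)
        return out

    @property
    def sequence(self) -> str:
        pieces = self.pieces
        return max(pieces, key=len) if pieces else ""

    def coverage_intervals(self) -> list[tuple[int, int]]:
        return [(c.scaffold_start, c.scaffold_end) for c in self.contigs]


# ---------------------------------------------------------------------------
# placement
# ---------------------------------------------------------------------------


def _align_infix(query: str, target: str):
    """Best infix placement of the whole query inside the target.

    Returns (edit_distance, start, end) with end exclusive, or None.
    """
    res = edlib.align(query, target, mode="HW", task="locations")
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    start, end = min(res["locations"])  # leftmost optimal location
    return res["editDistance"], int(start), int(end) + 1


def place_fragments(
    fragments: Sequence[Fragment],
    z_cdna: str,
    min_identity: float = 0.8,
    min_length: int = 50,
) -> ScaffoldLayout:
    """Place each fragment on the Z cDNA in its best orientation.

    A fragment is placed when its best full-length infix alignment reaches
    ``min_identity`` over at least ``min_length`` bases; ties between
    orientations favour '+', ties between locations the leftmost.  Unplaced
    fragments are reported, not dropped silently.
    """
    z = check_dna(z_cdna, "z_cdna")
    placements, unplaced = [], []
    for frag in fragments:
        if len(frag.sequence) < min_length:
            unplaced.append(frag.id)
            continue
        best = None
        for orient, seq in (("+", frag.sequence), ("-", revcomp(frag.sequence))):
            hit = _align_infix(seq, z)
            if hit is None:
                continue
            dist, start, end = hit
            key = (dist, start, 0 if orient == "+" else 1)
            if best is None or key < best[0]:
                best = (key, orient, seq, dist, start, end)
        if best is None:
            unplaced.append(frag.id)
            continue
        _, orient, seq, dist, start, end = best
        span = max(len(seq), end - start)
        identity = 1.0 - dist / span
        if identity < min_identity:
            unplaced.append(frag.id)
            continue
        placements.append(
            Placement(
                fragment_id=frag.id,
                orientation=orient,
                scaffold_start=start,
                scaffold_end=end,
                identity=identity,
                sequence=seq,
                source=frag.source,
            )
        )
    placements.sort(key=lambda p: (p.scaffold_start, p.scaffold_end, p.fragment_id))
    return ScaffoldLayout(scaffold_length=len(z), placements=placements,
                          unplaced=unplaced)


# ---------------------------------------------------------------------------
# overlap merging
# ---------------------------------------------------------------------------


def _identity_at(contig: str, frag: str, pos: int) -> tuple[int, float]:
    """Overlap length and identity of ``frag`` laid onto ``contig`` at pos."""
    ov = min(len(contig) - pos, len(frag))
    if ov <= 0:
        return 0, 0.0
    a, b = contig[pos : pos + ov], frag[:ov]
    matches = sum(x == y for x, y in zip(a, b))
    return ov, matches / ov


def _best_splice(contig: str, frag: str, expected_pos: int, radius: int = 15
                 ) -> tuple[int, int, float]:
    """Search positions near the scaffold-predicted one for the best splice."""
    best = (expected_pos, 0, -1.0)
    lo = max(0, expected_pos - radius)
    hi = min(len(contig), expected_pos + radius)
    for pos in range(lo, hi + 1):
        ov, ident = _identity_at(contig, frag, pos)
        if ident > best[2] or (ident == best[2] and ov > best[1]):
            best = (pos, ov, ident)
    return best


class _ContigBuilder:
    def __init__(self, p: Placement):
        self.seq = list(p.sequence)
        self.scaffold_start = p.scaffold_start
        self.scaffold_end = p.scaffold_end
        self.depth = np.ones(len(p.sequence), dtype=int)
        self.provenance = [(0, len(p.sequence), p.fragment_id, p.source)]
        self.best_source = {i: p.source for i in range(len(p.sequence))}

    def overlay(self, p: Placement, pos: int) -> int:
        """Lay the placement's sequence onto the contig starting at pos.

        Per-column consensus is an incremental majority vote: an incoming
        base replaces the current one only if it outvotes the accumulated
        depth, with ties broken by source priority (curated annotation wins
        over assemblies).  Returns the number of disagreeing columns.
        """
        frag = p.sequence
        ov = min(len(self.seq) - pos, len(frag))
        disagreements = 0
        for i in range(ov):
            col = pos + i
            if self.seq[col] != frag[i]:
                disagreements += 1
                cur_pri = _SOURCE_PRIORITY.get(self.best_source.get(col), 99)
                new_pri = _SOURCE_PRIORITY.get(p.source, 99)
                if self.depth[col] == 1 and new_pri < cur_pri:
                    self.seq[col] = frag[i]
                    self.best_source[col] = p.source
            self.depth[col] += 1
        if ov < len(frag):  # extension beyond current contig end
            self.seq.extend(frag[ov:])
            self.depth = np.concatenate(
                [self.depth, np.ones(len(frag) - ov, dtype=int)]
            )
            for i in range(ov, len(frag)):
                self.best_source[pos + i] = p.source
        self.provenance.append((pos, pos + len(frag), p.fragment_id, p.source))
        self.scaffold_end = max(self.scaffold_end, p.scaffold_end)
        return disagreements

    def build(self) -> Contig:
        return Contig(
            sequence="".join(self.seq),
            scaffold_start=self.scaffold_start,
            scaffold_end=self.scaffold_end,
            depth=self.depth,
            provenance=self.provenance,
        )


def merge_overlaps(
    layout: ScaffoldLayout,
    min_overlap: int = 40,
    min_identity: float = 0.95,
) -> MergedTranscript:
    """Join placements that overlap confidently into consensus contigs.

    Adjacent placements are spliced when their sequences overlap by at least
    ``min_overlap`` bases at ``min_identity`` or better; overlaps that exist
    on the scaffold but disagree in sequence are conflicts — both sides are
    kept as separate contigs.
    """
    merged = MergedTranscript()
    if not layout.placements:
        return merged
    contigs: list[Contig] = []
    conflicts: list[str] = []
    builder = _ContigBuilder(layout.placements[0])
    for p in layout.placements[1:]:
        scaffold_overlap = builder.scaffold_end - p.scaffold_start
        if scaffold_overlap >= min_overlap:
            expected = len(builder.seq) - scaffold_overlap
            pos, ov, ident = _best_splice("".join(builder.seq), p.sequence, expected)
            if ov >= min_overlap and ident >= min_identity:
                builder.overlay(p, pos)
                continue
            conflicts.append(
                f"overlap of {p.fragment_id} disagrees with contig "
                f"(identity {max(ident, 0):.2f} over {ov} bp)"
            )
        contigs.append(builder.build())
        builder = _ContigBuilder(p)
    contigs.append(builder.build())
    merged.contigs = contigs
    merged.bridges = [None] * (len(contigs) - 1)
    merged.conflicts = conflicts
    return merged


# ---------------------------------------------------------------------------
# gap bridging
# ---------------------------------------------------------------------------


def _z_orf_span(z_cdna: str) -> tuple[int, int]:
    """Longest forward-frame ORF of the Z cDNA (whole sequence if none)."""
    try:
        orfs = [o for o in find_orfs(z_cdna, min_aa=10) if o.frame > 0]
    except ValueError:
        orfs = []
    if not orfs:
        return 0, len(z_cdna)
    best = max(orfs, key=lambda o: o.end - o.start)
    return best.start, best.end


def _covered(intervals, span) -> float:
    a, b = span
    if b <= a:
        return 1.0
    covered = 0
    for s, e in sorted(intervals):
        covered += max(0, min(e, b) - max(s, a))
    return min(1.0, covered / (b - a))


def bridge_gaps(
    merged: MergedTranscript, layout: ScaffoldLayout, z_cdna: str
) -> MergedTranscript:
    """Join non-overlapping adjacent contigs with N-runs.

    The N-run length is the Z-scaffold distance between the contigs.  A
    negative inferred gap (conflicting placements) leaves the contigs
    unjoined and is reported.  Completeness is recomputed as the fraction
    of the Z ORF span covered by non-N consensus.
    """
    z = check_dna(z_cdna, "z_cdna")
    bridges = []
    for left, right in zip(merged.contigs, merged.contigs[1:]):
        gap = right.scaffold_start - left.scaffold_end
        if gap < 0:
            bridges.append(None)
            merged.conflicts.append(
                f"negative gap ({gap}) between contigs at "
                f"{left.scaffold_end} and {right.scaffold_start}: left unjoined"
            )
        else:
            bridges.append(gap)
    merged.bridges = bridges

    # bridged intervals on the primary (longest) piece
    intervals = []
    pos = 0
    cur_len = len(merged.contigs[0].sequence) if merged.contigs else 0
    piece_intervals: list = []
    best_len, best_intervals = cur_len, []
    for i, contig in enumerate(merged.contigs[1:]):
        gap = bridges[i]
        if gap is None:
            if cur_len > best_len:
                best_len, best_intervals = cur_len, piece_intervals
            piece_intervals, cur_len = [], len(contig.sequence)
        else:
            piece_intervals.append((cur_len, cur_len + gap))
            cur_len += gap + len(contig.sequence)
    if cur_len > best_len or not merged.contigs:
        best_len, best_intervals = cur_len, piece_intervals
    merged.bridged_intervals = best_intervals

    merged.completeness = _covered(merged.coverage_intervals(), _z_orf_span(z))
    return merged


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------


def _dedupe(fragments: Sequence[Fragment]) -> list[Fragment]:
    """Drop exact duplicates across sources (orientation-insensitive)."""
    ordered = sorted(
        fragments,
        key=lambda f: (_SOURCE_PRIORITY.get(f.source, 99), f.id),
    )
    seen, out = set(), []
    for f in ordered:
        key = min(f.sequence, revcomp(f.sequence))
        if key in seen:
            continue
        seen.add(key)
        out.append(f)
    return out


def assemble_w_transcript(
    fragments: Sequence[Fragment],
    z_cdna: str,
    min_identity: float = 0.8,
    min_overlap: int = 40,
    merge_identity: float = 0.95,
) -> tuple[MergedTranscript, dict]:
    """place → merge → bridge, with duplicate removal and a run report.

    The report carries the per-source contribution intervals (consensus
    track structure), the longest forward-frame ORF of the final consensus,
    unplaced fragments and conflicts.
    """
    if not fragments:
        raise ValueError("no fragments supplied")
    unique = _dedupe(fragments)
    layout = place_fragments(unique, z_cdna, min_identity=min_identity)
    merged = merge_overlaps(layout, min_overlap=min_overlap,
                            min_identity=merge_identity)
    if merged.contigs:
        merged = bridge_gaps(merged, layout, z_cdna)

    per_source: dict[str, list] = {}
    for p in layout.placements:
        per_source.setdefault(p.source, []).append(
            (p.scaffold_start, p.scaffold_end)
        )
    consensus = merged.sequence
    orf: Optional[OrfHit] = None
    plain = consensus.replace("N", "")
    if len(plain) >= 33:
        fwd = [o for o in find_orfs(consensus, min_aa=10) if o.frame > 0]
        orf = max(fwd, key=lambda o: o.end - o.start) if fwd else None
    report = {
        "n_fragments_in": len(fragments),
        "n_unique": len(unique),
        "n_placed": len(layout.placements),
        "unplaced": list(layout.unplaced),
        "per_source_intervals": per_source,
        "n_contigs": len(merged.contigs),
        "conflicts": list(merged.conflicts),
        "completeness": merged.completeness,
        "orf": None
        if orf is None
        else {"start": orf.start, "end": orf.end, "frame": orf.frame,
              "protein_length": len(orf.protein)},
    }
    if not layout.placements:
        report["diagnostic"] = "no fragment could be placed on the scaffold"
    return merged, report
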