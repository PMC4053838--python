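"""Discovery of candidate W-linked transcripts.

Mis-annotated W genes betray themselves by female-restricted expression, but
a female-specific pool from an unfinished genome is contaminated with
endogenous retroviral elements and decayed pseudogene copies.  This module
provides the screen and the two filters:

* :func:`female_specific_screen` — expressed in females (FPKM above a floor
  in at least one tissue) and silent in males (below a ceiling everywhere);
* :func:`retroviral_filter` — drop candidates with an ORF whose local
  protein alignment against a retroviral panel reaches e-value < 0.001
  (Karlin–Altschul statistics with ungapped defaults λ=0.267, K=0.041);
* :func:`pseudogene_filter` — drop candidates whose best match to a known
  gametologue protein covers less than half of it, or contains an in-frame
  stop within the aligned span.

ORFs are scanned in all six frames because de-novo fragments have unknown
orientation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

from .codons import CODON_TO_AA
from .core import Fragment, check_dna, revcomp

__all__ = [
    "OrfHit",
    "find_orfs",
    "female_specific_screen",
    "retroviral_filter",
    "pseudogene_filter",
    "load_default_panel",
    "protein_evalue",
]

# Karlin-Altschul parameters for ungapped BLOSUM62 protein alignment
KA_LAMBDA = 0.267
KA_K = 0.041

_PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYXBZJUO*")


@dataclass
class OrfHit:
    """One open reading frame, with optional best-panel alignment stats.

    ``start``/``end`` are 0-based half-open on the forward strand of the
    transcript and span the coding part only (the stop codon is excluded),
    so ``end - start == 3 * len(protein)``.
    """

    frame: int  # +1 +2 +3 -1 -2 -3
    start: int
    end: int
    protein: str
    score_bits: Optional[float] = None
    evalue: Optional[float] = None
    best_panel: Optional[str] = None


def _translate_frame(seq: str, frame0: int) -> str:
    """Translate one forward frame; codons containing N become 'X'."""
    aas = []
    for i in range(frame0, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        aas.append(CODON_TO_AA.get(codon, "X"))
    return "".join(aas)


def find_orfs(sequence: str, min_aa: int = 30) -> list[OrfHit]:
    """All maximal ATG→stop ORFs of length >= ``min_aa`` in six frames.

    Maximal means the ORF starts at the first ATG following the previous
    stop (nested later ATGs are not reported separately).  A trailing ORF
    that runs off the end of the sequence without a stop is included.
    """
    if min_aa < 10:
        raise ValueError("min_aa must be >= 10")
    seq = check_dna(sequence)
    L = len(seq)
    hits: list[OrfHit] = []
    for strand in (+1, -1):
        s = seq if strand == +1 else revcomp(seq)
        for f in range(3):
            prot = _translate_frame(s, f)
            i = 0
            n = len(prot)
            while i < n:
                if prot[i] != "M":
                    i += 1
                    continue
                j = i
                while j < n and prot[j] != "*":
                    j += 1
                has_stop = j < n
                aa = prot[i:j]
                # a trailing ORF counts only if it reaches the sequence end
                if (has_stop or f + 3 * j >= L - 2) and len(aa) >= min_aa:
                    s0 = f + 3 * i
                    s1 = f + 3 * j
                    if strand == +1:
                        start, end = s0, s1
                    else:
                        start, end = L - s1, L - s0
                    hits.append(
                        OrfHit(frame=strand * (f + 1), start=start, end=end,
                               protein=aa)
                    )
                i = j + 1
    hits.sort(key=lambda h: (h.start, h.end, h.frame))
    return hits


# ---------------------------------------------------------------------------
# female-specificity screen
# ---------------------------------------------------------------------------


def female_specific_screen(
    candidates: Sequence[Fragment],
    fpkm: pd.DataFrame,
    design: pd.DataFrame,
    expressed_floor: float = 1.0,
    male_ceiling: float = 0.1,
) -> pd.DataFrame:
    """Flag candidates expressed in females and silent in males.

    A candidate is flagged when its mean female FPKM reaches
    ``expressed_floor`` in at least one tissue AND its mean male FPKM stays
    at or below ``male_ceiling`` in every tissue.  Returns a per-candidate
    table with the summaries and the flag.
    """
    for sex in ("F", "M"):
        if not (design["sex"] == sex).any():
            raise ValueError(f"design has no {sex} samples")
    tissues = sorted(design["tissue"].unique())
    rows = []
    for cand in candidates:
        if cand.id not in fpkm.index:
            raise KeyError(f"candidate {cand.id!r} missing from FPKM table")
        row = {"candidate_id": cand.id}
        fem_ok, male_ok = False, True
        for t in tissues:
            for sex in ("F", "M"):
                sel = design.index[(design["tissue"] == t) & (design["sex"] == sex)]
                v = float(fpkm.loc[cand.id, sel].mean())
                row[f"fpkm_{t}_{sex}"] = v
                if sex == "F" and v >= expressed_floor:
                    fem_ok = True
                if sex == "M" and v > male_ceiling:
                    male_ok = False
        row["female_specific"] = fem_ok and male_ok
        rows.append(row)
    return pd.DataFrame(rows).set_index("candidate_id")


# ---------------------------------------------------------------------------
# homology machinery
# ---------------------------------------------------------------------------


def _protein_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def protein_evalue(score: float, m: int, n: int) -> tuple[float, float]:
    """(bit score, e-value) from a raw local alignment score.

    Karlin–Altschul: S' = (λS − ln K)/ln 2 and E = m·n·2^(−S').
    """
    bits = (KA_LAMBDA * score - math.log(KA_K)) / math.log(2.0)
    evalue = m * n * 2.0 ** (-bits)
    return bits, evalue


def _check_panel(panel: Sequence[tuple[str, str]]) -> list[tuple[str, str]]:
    if not panel:
        raise ValueError("protein panel is empty")
    out = []
    for pid, prot in panel:
        prot = prot.upper()
        bad = set(prot) - _PROTEIN_ALPHABET
        if bad:
            raise ValueError(f"panel entry {pid!r} has invalid characters {sorted(bad)}")
        out.append((pid, prot))
    return out


def load_default_panel() -> list[tuple[str, str]]:
    """The packaged synthetic retroviral-like toy protein panel."""
    ref = resources.files("wseq.data") / "retroviral_panel_synthetic.fasta"
    with ref.open() as fh:
        return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(fh, "fasta")]


def retroviral_filter(
    candidates: Sequence[Fragment],
    protein_panel: Sequence[tuple[str, str]],
    evalue_threshold: float = 1e-3,
    min_aa: int = 30,
) -> tuple[list[Fragment], list[Fragment], pd.DataFrame]:
    """Remove candidates with an ORF homologous to a retroviral protein.

    Every ORF of every candidate is locally aligned (BLOSUM62, affine gaps
    11/1) against every panel protein; the candidate is removed iff any ORF
    reaches e-value below ``evalue_threshold``.  Returns (retained, removed,
    report).
    """
    panel = _check_panel(protein_panel)
    aligner = _protein_aligner()
    retained, removed, rows = [], [], []
    for cand in candidates:
        best = (math.inf, None, None)  # evalue, panel id, bits
        for orf in find_orfs(cand.sequence, min_aa=min_aa):
            for pid, prot in panel:
                score = aligner.score(orf.protein, prot)
                bits, ev = protein_evalue(score, len(orf.protein), len(prot))
                if ev < best[0]:
                    best = (ev, pid, bits)
        hit = best[0] < evalue_threshold
        (removed if hit else retained).append(cand)
        rows.append(
            {
                "candidate_id": cand.id,
                "decision": "removed" if hit else "retained",
                "reason": "retroviral-homology" if hit else "",
                "best_evalue": best[0] if best[1] is not None else np.nan,
                "best_panel": best[1] or "",
            }
        )
    report = pd.DataFrame(rows).set_index("candidate_id")
    return retained, removed, report


def pseudogene_filter(
    candidates: Sequence[Fragment],
    gametologue_proteins: Sequence[tuple[str, str]],
    min_coverage: float = 0.5,
    evalue_threshold: float = 1e-3,
) -> tuple[list[Fragment], list[Fragment], pd.DataFrame]:
    """Remove decayed copies of known gametologue proteins.

    Each candidate's six frame translations (stops rendered as X for
    alignment) are locally aligned against every gametologue protein.  A
    candidate with a confident best match (e-value below
    ``evalue_threshold``, so chance local hits do not qualify) is removed
    when the aligned span covers less than ``min_coverage`` of the
    gametologue protein, or the matching frame holds an internal stop within
    the aligned span.  Candidates with no confident match are retained.
    """
    panel = _check_panel(gametologue_proteins)
    aligner = _protein_aligner()
    retained, removed, rows = [], [], []
    for cand in candidates:
        seq = check_dna(cand.sequence)
        frames = {}
        for strand in (+1, -1):
            s = seq if strand == +1 else revcomp(seq)
            for f in range(3):
                frames[strand * (f + 1)] = _translate_frame(s, f)
        best = None  # (score, frame, alignment, pid, gam_len)
        for frame, prot in frames.items():
            masked = prot.replace("*", "X")
            if not masked:
                continue
            for pid, gam in panel:
                alns = aligner.align(masked, gam)
                if alns.score <= 0:
                    continue
                if best is None or alns.score > best[0]:
                    best = (alns.score, frame, alns[0], pid, len(gam), prot)
        reason = ""
        confident = False
        if best is not None:
            _, ev = protein_evalue(best[0], len(best[5]), best[4])
            confident = ev < evalue_threshold
        if confident:
            score, frame, aln, pid, gam_len, prot = best
            qs, qe = aln.aligned[0][0][0], aln.aligned[0][-1][1]
            ts, te = aln.aligned[1][0][0], aln.aligned[1][-1][1]
            coverage = (te - ts) / gam_len
            internal_stops = prot[qs:qe].count("*")
            if coverage < min_coverage:
                reason = f"low-coverage ({coverage:.2f} of {pid})"
            elif internal_stops:
                reason = f"internal-stops ({internal_stops} in span vs {pid})"
        hit = bool(reason)
        (removed if hit else retained).append(cand)
        rows.append(
            {
                "candidate_id": cand.id,
                "decision": "removed" if hit else "retained",
                "reason": reason if hit else "",
                "best_match": best[3] if best is not None else "",
                "best_score": best[0] if best is not None else np.nan,
            }
        )
    report = pd.DataFrame(rows).set_index("candidate_id")
    return retained, removed, report
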