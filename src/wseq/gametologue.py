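"""W/Z gametologue divergence and combined-expression comparison.

After recombination between Z and W stopped, each surviving W gene has been
diverging from its Z partner under mostly purifying selection.  This module
quantifies that divergence per pair:

* global DNA / protein identity (end-gap-free alignment);
* dN, dS and ω by the Nei–Gojobori counting method: synonymous site
  fractions per codon position, observed differences partitioned over all
  equally weighted minimal mutational pathways (pathways through stop
  codons excluded), and a Jukes–Cantor multiple-hit correction
  d = −3/4·ln(1 − 4p/3);
* a sliding-window ω profile along the codon alignment;
* the combined-expression comparison: W+Z in females vs the two Z copies in
  males, tested with the negative-binomial sex test on summed counts.

ω sentinels follow the reporting convention of the W gene catalog:
dN = 0 is printed as 0.000 regardless of dS ("zero"); dS = 0 with dN > 0 is
"undefined" (never infinity); p ≥ 3/4 makes the Jukes–Cantor log argument
non-positive ("saturated").
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import permutations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices

from .codons import CODON_TO_AA, NUCLEOTIDES, is_stop, split_codons, translate_cds
from .core import CountExperiment, check_dna

__all__ = [
    "NeiGojoboriResult",
    "GametologueComparison",
    "CombinedExpressionVerdict",
    "global_align_identity",
    "find_z_gametologue",
    "codon_align",
    "nei_gojobori_dnds",
    "sliding_window_dnds",
    "compare_pair",
    "combined_expression_compare",
]


# ---------------------------------------------------------------------------
# alignment and identity
# ---------------------------------------------------------------------------


def _dna_aligner(mode: str) -> PairwiseAligner:
    a = PairwiseAligner()
    a.mode = mode
    a.match_score = 2.0
    a.mismatch_score = -3.0
    a.open_gap_score = -5.0
    a.extend_gap_score = -2.0
    if mode == "global":
        a.end_insertion_score = 0.0
        a.end_deletion_score = 0.0
    return a


def _protein_global_aligner() -> PairwiseAligner:
    a = PairwiseAligner()
    a.mode = "global"
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = -11.0
    a.extend_gap_score = -1.0
    a.end_insertion_score = 0.0
    a.end_deletion_score = 0.0
    return a


def _identity_from_alignment(aln) -> float:
    """Identity % over aligned columns, terminal gaps excluded."""
    ta, qa = aln.aligned  # blocks on target and query
    if len(ta) == 0:
        return 0.0
    target, query = str(aln.target), str(aln.query)
    matches = 0
    aligned_cols = 0
    for (ts, te), (qs, qe) in zip(ta, qa):
        aligned_cols += te - ts
        matches += sum(
            1 for a, b in zip(target[ts:te], query[qs:qe]) if a == b
        )
    # internal gap columns: unaligned stretches between successive blocks
    for i in range(1, len(ta)):
        aligned_cols += (ta[i][0] - ta[i - 1][1]) + (qa[i][0] - qa[i - 1][1])
    return 100.0 * matches / aligned_cols


def global_align_identity(seq_a: str, seq_b: str, alphabet: str = "dna") -> float:
    """Percent identity from an end-gap-free global alignment.

    DNA scoring +2/−3 with gaps −5/−2; protein scoring BLOSUM62 with gaps
    −11/−1.  Identity is matches over aligned columns, not counting
    terminal overhangs.
    """
    if alphabet == "dna":
        a = check_dna(seq_a, "seq_a")
        b = check_dna(seq_b, "seq_b")
        aligner = _dna_aligner("global")
    elif alphabet == "protein":
        a, b = seq_a.upper(), seq_b.upper()
        valid = set("ACDEFGHIKLMNPQRSTVWYXBZ")
        if (set(a) | set(b)) - valid:
            raise ValueError("invalid protein characters")
        aligner = _protein_global_aligner()
    else:
        raise ValueError(f"unknown alphabet {alphabet!r}")
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    return _identity_from_alignment(aligner.align(a, b)[0])


def find_z_gametologue(
    w_transcript: str,
    z_transcripts: Sequence[tuple[str, str]],
    min_coverage: float = 0.5,
) -> Optional[dict]:
    """Best Z homologue of a W transcript, or None.

    Candidates are ranked by local DNA alignment score; the winner must
    cover at least ``min_coverage`` of *both* sequences (reciprocal
    coverage), which rejects spurious short repeats — and, for genuinely
    novel W genes with no Z partner, returns None.
    """
    if not z_transcripts:
        raise ValueError("empty Z transcript set")
    w = check_dna(w_transcript, "w_transcript")
    aligner = _dna_aligner("local")
    best = None
    for zid, zseq in z_transcripts:
        z = check_dna(zseq, f"z transcript {zid}")
        aln = aligner.align(w, z)
        if aln.score <= 0:
            continue
        top = aln[0]
        ta, qa = top.aligned
        w_span = ta[-1][1] - ta[0][0]
        z_span = qa[-1][1] - qa[0][0]
        cov_w, cov_z = w_span / len(w), z_span / len(z)
        if cov_w < min_coverage or cov_z < min_coverage:
            continue
        if best is None or top.score > best["score"]:
            best = {
                "z_id": zid,
                "score": float(top.score),
                "identity": _identity_from_alignment(top),
                "coverage_w": cov_w,
                "coverage_z": cov_z,
            }
    return best


def codon_align(cds_a: str, cds_b: str) -> tuple[str, str]:
    """Codon-aware alignment: align translations, back-map, drop gapped codons.

    Returns two equal-length, gap-free, frame-preserving codon strings ready
    for :func:`nei_gojobori_dnds`.
    """
    a = check_dna(cds_a, "cds_a")
    b = check_dna(cds_b, "cds_b")
    pa, pb = translate_cds(a), translate_cds(b)
    if "*" in pa or "*" in pb:
        raise ValueError("internal stop codon in CDS")
    aln = _protein_global_aligner().align(pa, pb)[0]
    ta, qa = aln.aligned
    out_a, out_b = [], []
    for (ts, te), (qs, qe) in zip(ta, qa):
        out_a.append(a[3 * ts : 3 * te])
        out_b.append(b[3 * qs : 3 * qe])
    return "".join(out_a), "".join(out_b)


# ---------------------------------------------------------------------------
# Nei-Gojobori dN/dS
# ---------------------------------------------------------------------------


@dataclass
class NeiGojoboriResult:
    dn: float
    ds: float
    omega: Optional[float]          # None when undefined/saturated
    status: str                     # ok | zero | undefined | saturated
    s_sites: float = 0.0
    n_sites: float = 0.0
    sd: float = 0.0
    nd: float = 0.0

    def omega_printed(self) -> str:
        """Catalog convention: dN=0 prints 0.000; undefined prints 'NA'."""
        if self.status in ("ok", "zero"):
            return f"{0.0 if self.omega is None else self.omega:.3f}"
        return "NA"


def _codon_site_counts(codon: str) -> float:
    """Synonymous site count of one codon (out of 3).

    For each position, the fraction of the three single-nucleotide changes
    that are synonymous; changes creating a stop codon count as
    nonsynonymous.
    """
    aa = CODON_TO_AA[codon]
    syn = 0.0
    for i in range(3):
        for nt in NUCLEOTIDES:
            if nt == codon[i]:
                continue
            alt = codon[:i] + nt + codon[i + 1 :]
            if not is_stop(alt) and CODON_TO_AA[alt] == aa:
                syn += 1.0
    return syn / 3.0


def _pathway_steps(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons.

    Codons differing at several positions average over all orderings of the
    single changes; orderings passing through a stop codon are excluded
    (weights renormalised over the remainder — if every ordering is blocked
    the stop-containing ones are used anyway, so counts never vanish).
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff):
        cur = c1
        steps = []
        blocked = False
        for i in order:
            nxt = cur[:i] + c2[i] + cur[i + 1 :]
            if is_stop(nxt) and nxt != c2:
                blocked = True
            steps.append((cur, nxt))
            cur = nxt
        paths.append((blocked, steps))
    usable = [steps for blocked, steps in paths if not blocked]
    if not usable:
        usable = [steps for _, steps in paths]
    w = 1.0 / len(usable)
    sd = nd = 0.0
    for steps in usable:
        for cur, nxt in steps:
            if CODON_TO_AA.get(cur) == CODON_TO_AA.get(nxt):
                sd += w
            else:
                nd += w
    return sd, nd


def _jukes_cantor(p: float) -> Optional[float]:
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def nei_gojobori_dnds(w_cds: str, z_cds: str) -> NeiGojoboriResult:
    """Counting-method dN/dS for a codon-aligned, gap-free CDS pair.

    Sites are averaged over the two sequences; observed differences are
    partitioned over equally weighted minimal mutational pathways; p
    distances are Jukes–Cantor corrected.  Symmetric in its arguments.
    """
    a = check_dna(w_cds, "w_cds")
    b = check_dna(z_cds, "z_cds")
    if len(a) != len(b):
        raise ValueError("CDS pair must be codon-aligned to equal length")
    ca, cb = split_codons(a), split_codons(b)
    for codons, name in ((ca, "w_cds"), (cb, "z_cds")):
        for i, c in enumerate(codons):
            if is_stop(c):
                raise ValueError(f"internal stop codon in {name} at codon {i}")

    s_sites = sum(map(_codon_site_counts, ca)) / 2.0 + sum(
        map(_codon_site_counts, cb)
    ) / 2.0
    n_sites = 3.0 * len(ca) - s_sites
    sd = nd = 0.0
    for c1, c2 in zip(ca, cb):
        s, n = _pathway_steps(c1, c2)
        sd += s
        nd += n

    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ds = _jukes_cantor(ps)
    dn = _jukes_cantor(pn)
    if dn is None or ds is None:
        return NeiGojoboriResult(
            dn=np.nan if dn is None else dn,
            ds=np.nan if ds is None else ds,
            omega=None, status="saturated",
            s_sites=s_sites, n_sites=n_sites, sd=sd, nd=nd,
        )
    if dn == 0.0:
        return NeiGojoboriResult(dn=0.0, ds=ds, omega=0.0, status="zero",
                                 s_sites=s_sites, n_sites=n_sites, sd=sd, nd=nd)
    if ds == 0.0:
        return NeiGojoboriResult(dn=dn, ds=0.0, omega=None, status="undefined",
                                 s_sites=s_sites, n_sites=n_sites, sd=sd, nd=nd)
    return NeiGojoboriResult(dn=dn, ds=ds, omega=dn / ds, status="ok",
                             s_sites=s_sites, n_sites=n_sites, sd=sd, nd=nd)


def sliding_window_dnds(
    w_cds: str,
    z_cds: str,
    window_codons: int = 50,
    step_codons: int = 10,
) -> list[tuple[float, Optional[float]]]:
    """Per-window ω along the codon alignment.

    Each entry is (window midpoint in codons, ω); windows whose estimate is
    undefined or saturated carry None but keep their place on the axis.
    A window longer than the alignment collapses to one whole-gene window
    (with a warning).
    """
    if len(w_cds) != len(z_cds):
        raise ValueError("CDS pair must be codon-aligned to equal length")
    n_codons = len(w_cds) // 3
    if window_codons > n_codons:
        warnings.warn(
            f"window ({window_codons} codons) longer than alignment "
            f"({n_codons}): using a single whole-gene window"
        )
        window_codons = n_codons
    profile = []
    for start in range(0, n_codons - window_codons + 1, step_codons):
        end = start + window_codons
        res = nei_gojobori_dnds(
            w_cds[3 * start : 3 * end], z_cds[3 * start : 3 * end]
        )
        omega = res.omega if res.status in ("ok", "zero") else None
        profile.append((start + window_codons / 2.0, omega))
    return profile


# ---------------------------------------------------------------------------
# pair-level summary
# ---------------------------------------------------------------------------


@dataclass
class GametologueComparison:
    pair_id: str
    dna_identity: float
    protein_identity: float
    dn: float
    ds: float
    omega: Optional[float]
    omega_status: str
    window_profile: list = field(default_factory=list)


def compare_pair(
    pair_id: str,
    w_cds: str,
    z_cds: str,
    window_codons: int = 50,
    step_codons: int = 10,
) -> GametologueComparison:
    """Full divergence summary for one W/Z pair (alignment done here)."""
    wa, za = codon_align(w_cds, z_cds)
    res = nei_gojobori_dnds(wa, za)
    profile = sliding_window_dnds(wa, za, window_codons, step_codons)
    return GametologueComparison(
        pair_id=pair_id,
        dna_identity=global_align_identity(w_cds, z_cds, "dna"),
        protein_identity=global_align_identity(
            translate_cds(wa), translate_cds(za), "protein"
        ),
        dn=res.dn,
        ds=res.ds,
        omega=res.omega,
        omega_status=res.status,
        window_profile=profile,
    )


# ---------------------------------------------------------------------------
# combined expression (W+Z females vs ZZ males)
# ---------------------------------------------------------------------------


@dataclass
class CombinedExpressionVerdict:
    pair_id: str
    female_total: dict          # tissue -> mean female combined CPM (or FPKM)
    male_total: dict            # tissue -> mean male Z CPM (or FPKM)
    w_share: dict               # tissue -> W fraction of the female total
    pvalue: dict                # tissue -> NB sex-test p on summed counts
    significant: dict           # tissue -> p < alpha
    alpha: float = 0.01


def combined_expression_compare(
    pair_id: str,
    w_counts: pd.Series,
    z_counts: pd.Series,
    design: pd.DataFrame,
    library_sizes: pd.Series,
    dispersion: float = 0.1,
    alpha: float = 0.01,
    w_length: Optional[float] = None,
    z_length: Optional[float] = None,
) -> CombinedExpressionVerdict:
    """Compare female W+Z expression against male ZZ expression.

    Per sample the combined count is W+Z for females and Z for males (the
    male W count is structurally zero); the per-tissue significance is the
    negative-binomial sex LRT applied to that one combined gene, flagged at
    ``alpha`` (raw p).  Totals and the female W share are reported as mean
    CPM, or as FPKM when both gene lengths are given.
    """
    from .dimorphism import DispersionEstimates, test_sex_within_tissue

    for s in design.index:
        if s not in w_counts.index or s not in z_counts.index:
            raise ValueError(f"sample {s!r} missing from pair counts")
    female = design["sex"] == "F"
    combined = z_counts.astype(float).copy()
    combined[female] = combined[female] + w_counts[female]

    counts = pd.DataFrame([combined.round().astype(int)], index=[pair_id])
    counts.columns = design.index
    exp = CountExperiment(
        counts=counts, design=design.copy(),
        library_sizes=library_sizes.copy(),
    )
    disp = DispersionEstimates(
        common_dispersion=dispersion,
        tagwise_dispersions=pd.Series([dispersion], index=[pair_id]),
    )

    def norm(series, sel, length):
        v = (series[sel] / library_sizes[sel] * 1e6).mean()
        if length is not None:
            v /= length / 1e3
        return float(v)

    female_total, male_total, w_share, pvals, sig = {}, {}, {}, {}, {}
    for tissue in sorted(design["tissue"].unique()):
        res = test_sex_within_tissue(exp, disp, tissue,
                                     effective_library_sizes=library_sizes)
        p = float(res.table.loc[pair_id, "pvalue"])
        fs = design.index[(design["tissue"] == tissue) & female]
        ms = design.index[(design["tissue"] == tissue) & ~female]
        ftot_w = norm(w_counts, fs, w_length)
        ftot_z = norm(z_counts, fs, z_length)
        female_total[tissue] = ftot_w + ftot_z
        male_total[tissue] = norm(z_counts, ms, z_length)
        w_share[tissue] = ftot_w / (ftot_w + ftot_z) if (ftot_w + ftot_z) else 0.0
        pvals[tissue] = p
        sig[tissue] = p < alpha
    return CombinedExpressionVerdict(
        pair_id=pair_id, female_total=female_total, male_total=male_total,
        w_share=w_share, pvalue=pvals, significant=sig, alpha=alpha,
    )
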