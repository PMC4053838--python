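"""Synthetic ZW mini-genome generator.

Produces every input the downstream analyses consume, with the statistical
structure those analyses assume about early avian embryos:

* negative-binomial gene counts for a 2 tissue × 2 sex × 2 replicate design,
  with gene-wise dispersion spread log-normally around a prior;
* incomplete Z dosage compensation — non-compensated Z genes expressed at a
  configurable male:female mean ratio (default 1.6) in both tissues;
* strictly female-restricted W / W_random genes (hard zero counts in male
  samples by default; a leaky mode exists for robustness tests) and an
  MHM-like female-only Z locus;
* autosomal genes sexually dimorphic in exactly one tissue;
* codon-evolved W/Z gametologue pairs with a target dN/dS (ω);
* transcripts fragmented into partially overlapping pieces scattered over
  pseudo-chromosomes, emulating a broken genome assembly;
* retroviral decoy transcripts carrying an ORF homologous to a packaged
  toy gag/pol-like protein panel.

All randomness flows through a single integer seed; a fixed config + seed
reproduces outputs byte-identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .codons import (
    AA_TO_CODONS,
    CODON_TO_AA,
    NUCLEOTIDES,
    SENSE_CODONS,
    is_stop,
    split_codons,
    translate_cds,
)
from .core import (
    CHROM_CLASSES,
    FRAGMENT_SOURCES,
    CountExperiment,
    Fragment,
    SimTruth,
    TISSUES,
    W_CLASSES,
    revcomp,
)

__all__ = [
    "SimConfig",
    "simulate_counts",
    "random_cds",
    "simulate_gametologue_pair",
    "fragmentize",
    "make_retroviral_decoys",
    "build_candidate_pool",
]


@dataclass
class SimConfig:
    """Parameters of the synthetic experiment.

    Defaults are the study conditions of the embryonic chicken design this
    package models: 2 tissues × 2 sexes × 2 replicates, 1.6-fold male-biased
    non-compensated Z expression, strictly female W expression, ~20M
    fragments per library, and a biological coefficient of variation around
    0.2 (dispersion 0.04) typical of inbred-line RNA-seq replicates.
    """

    n_genes_per_class: dict = field(
        default_factory=lambda: {
            "autosome": 8000,
            "Z": 500,
            "W": 20,
            "W_random": 6,
            "Un_random": 80,
        }
    )
    n_replicates: int = 2
    z_noncompensated_fraction: float = 1.0
    z_male_ratio: float = 1.6
    n_mhm_genes: int = 2
    w_female_fpkm_range: tuple = (5.0, 500.0)
    w_male_leak_fpkm: float = 0.0
    dispersion_prior: float = 0.04
    dispersion_sigma: float = 0.5
    n_dimorphic_autosomal_per_tissue: int = 30
    dimorphic_fold_change: float = 4.0
    n_tissue_de_genes: int = 50
    tissue_fold_change: float = 5.0
    library_size: float = 20_000_000.0
    seed: int = 42

    def __post_init__(self) -> None:
        for name in ("z_noncompensated_fraction",):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        for name in (
            "z_male_ratio",
            "dimorphic_fold_change",
            "tissue_fold_change",
            "dispersion_prior",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")
        if self.library_size > 1e12:
            raise ValueError("library_size too large: counts would overflow")
        lo, hi = self.w_female_fpkm_range
        if not (0 < lo <= hi):
            raise ValueError("w_female_fpkm_range must be a positive interval")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        bad = set(self.n_genes_per_class) - set(CHROM_CLASSES)
        if bad:
            raise ValueError(f"unknown chromosome classes {sorted(bad)}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["w_female_fpkm_range"] = list(self.w_female_fpkm_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "w_female_fpkm_range" in d:
            d["w_female_fpkm_range"] = tuple(d["w_female_fpkm_range"])
        return cls(**d)


# ---------------------------------------------------------------------------
# count simulation
# ---------------------------------------------------------------------------


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """NB(mean=mu, var=mu+phi*mu^2) sample; Poisson where phi ~ 0."""
    mu = np.asarray(mu, dtype=float)
    phi = np.broadcast_to(np.asarray(phi, dtype=float), mu.shape)
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    pois = pos & (phi < 1e-8)
    nb = pos & ~pois
    if pois.any():
        out[pois] = rng.poisson(mu[pois])
    if nb.any():
        r = 1.0 / phi[nb]
        p = r / (r + mu[nb])
        out[nb] = rng.negative_binomial(r, p)
    return out


def simulate_counts(config: SimConfig) -> tuple[CountExperiment, SimTruth]:
    """Simulate a factorial NB count experiment plus its ground truth.

    Mean model per gene g and sample s (tissue t, sex x):
    ``mu = fpkm_g(t, x) * length_kb_g * libsize_s / 1e6``, with the sample
    library size jittered ±20% around ``config.library_size``.  Counts are
    NB with gene-wise dispersion drawn log-normally around
    ``dispersion_prior`` (sdlog ``dispersion_sigma``).
    """
    rng = np.random.default_rng(config.seed)

    classes: list[str] = []
    gene_ids: list[str] = []
    for cls in CHROM_CLASSES:  # fixed order for reproducibility
        n = int(config.n_genes_per_class.get(cls, 0))
        for i in range(n):
            classes.append(cls)
            gene_ids.append(f"{cls}_g{i:04d}")
    n_genes = len(gene_ids)
    if n_genes == 0:
        raise ValueError("no genes configured")
    cls_arr = np.array(classes)

    lengths = np.clip(
        rng.lognormal(mean=math.log(1500.0), sigma=0.5, size=n_genes), 200, 12000
    ).astype(int)
    len_kb = lengths / 1000.0

    # baseline female FPKM
    fpkm = rng.lognormal(mean=math.log(10.0), sigma=1.2, size=n_genes)
    is_w = np.isin(cls_arr, W_CLASSES)
    lo, hi = config.w_female_fpkm_range
    fpkm[is_w] = np.exp(rng.uniform(math.log(lo), math.log(hi), size=is_w.sum()))

    # male:female ratio per tissue (fc > 1 means male-biased)
    fc = {t: np.ones(n_genes) for t in TISSUES}
    sex_of_bias = np.array(["none"] * n_genes, dtype=object)

    z_idx = np.flatnonzero(cls_arr == "Z")
    n_mhm = min(config.n_mhm_genes, len(z_idx))
    mhm_idx = z_idx[:n_mhm]
    is_mhm = np.zeros(n_genes, dtype=bool)
    is_mhm[mhm_idx] = True
    z_rest = z_idx[n_mhm:]
    n_nc = int(round(config.z_noncompensated_fraction * len(z_rest)))
    nc_idx = z_rest[rng.permutation(len(z_rest))[:n_nc]]
    for t in TISSUES:
        fc[t][nc_idx] = config.z_male_ratio
    if config.z_male_ratio != 1.0:
        sex_of_bias[nc_idx] = "M"

    # W genes and the MHM locus: female-only
    female_only = is_w | is_mhm
    sex_of_bias[female_only] = "F"

    # autosomal genes dimorphic in exactly one tissue
    auto_idx = np.flatnonzero(cls_arr == "autosome")
    order = rng.permutation(len(auto_idx))
    k = config.n_dimorphic_autosomal_per_tissue
    dfc = config.dimorphic_fold_change
    picked = {
        "blastoderm": auto_idx[order[:k]],
        "gonad": auto_idx[order[k : 2 * k]],
    }
    for t, idx in picked.items():
        if dfc != 1.0:
            half = len(idx) // 2
            fc[t][idx[:half]] = 1.0 / dfc  # female-biased
            fc[t][idx[half:]] = dfc  # male-biased
            sex_of_bias[idx[:half]] = "F"
            sex_of_bias[idx[half:]] = "M"

    # tissue effect (gonad relative to blastoderm), autosomal background genes
    tissue_fc = np.ones(n_genes)
    pool = auto_idx[order[2 * k : 2 * k + config.n_tissue_de_genes]]
    if config.tissue_fold_change != 1.0 and len(pool):
        half = len(pool) // 2
        tissue_fc[pool[:half]] = config.tissue_fold_change
        tissue_fc[pool[half:]] = 1.0 / config.tissue_fold_change

    dispersion = rng.lognormal(
        mean=math.log(config.dispersion_prior), sigma=config.dispersion_sigma,
        size=n_genes,
    )

    # design and library sizes
    sample_names, tissues_s, sexes_s, reps_s = [], [], [], []
    for t in TISSUES:
        for x in ("F", "M"):
            for r in range(1, config.n_replicates + 1):
                sample_names.append(f"{t}_{x}_{r}")
                tissues_s.append(t)
                sexes_s.append(x)
                reps_s.append(r)
    lib = config.library_size * rng.uniform(0.8, 1.2, size=len(sample_names))

    leak = config.w_male_leak_fpkm
    counts = np.zeros((n_genes, len(sample_names)), dtype=np.int64)
    for j, (t, x) in enumerate(zip(tissues_s, sexes_s)):
        f = fpkm.copy()
        if t == "gonad":
            f = f * tissue_fc
        if x == "M":
            f = f * fc[t]
            f[female_only] = leak
        mu = f * len_kb * (lib[j] / 1e6)
        if np.nanmax(mu) > 1e15:
            raise ValueError("simulated means too large: counts would overflow")
        counts[:, j] = _nb_draw(rng, mu, dispersion)

    counts_df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"),
                             columns=sample_names)
    design = pd.DataFrame(
        {"tissue": tissues_s, "sex": sexes_s, "replicate": reps_s},
        index=pd.Index(sample_names, name="sample"),
    )
    annotation = pd.DataFrame(
        {"chrom_class": classes, "length": lengths},
        index=pd.Index(gene_ids, name="gene_id"),
    )
    experiment = CountExperiment(
        counts=counts_df,
        design=design,
        library_sizes=pd.Series(lib, index=sample_names),
        annotation=annotation,
    )

    dim = {t: (fc[t] != 1.0) | female_only for t in TISSUES}
    truth_genes = pd.DataFrame(
        {
            "chrom_class": classes,
            "length": lengths,
            "base_fpkm": fpkm,
            "is_dimorphic_blastoderm": dim["blastoderm"],
            "is_dimorphic_gonad": dim["gonad"],
            "sex_of_bias": sex_of_bias,
            "fc_blastoderm": np.where(female_only, 0.0, fc["blastoderm"]),
            "fc_gonad": np.where(female_only, 0.0, fc["gonad"]),
            "is_tissue_de": tissue_fc != 1.0,
            "tissue_fc": tissue_fc,
            "dispersion": dispersion,
            "is_mhm": is_mhm,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return experiment, SimTruth(genes=truth_genes)


# ---------------------------------------------------------------------------
# sequence simulation
# ---------------------------------------------------------------------------


def random_cds(n_codons: int, rng: np.random.Generator) -> str:
    """ATG followed by ``n_codons - 1`` random sense codons (no stop)."""
    if n_codons < 1:
        raise ValueError("need at least one codon")
    idx = rng.integers(0, len(SENSE_CODONS), size=n_codons - 1)
    return "ATG" + "".join(SENSE_CODONS[i] for i in idx)


def simulate_gametologue_pair(
    z_cds: str,
    omega: float,
    expected_subs_per_codon: float,
    seed: int | np.random.Generator,
) -> tuple[str, str]:
    """Evolve a W copy from a Z CDS under an ω-filtered substitution process.

    Single-nucleotide changes are proposed uniformly; a change is accepted
    with probability 1 if synonymous and ``omega`` if nonsynonymous; changes
    creating a stop codon are always rejected.  The process runs until
    ``round(expected_subs_per_codon * n_codons)`` substitutions have been
    accepted, so repeated hits at one site model multiple substitutions.

    Returns ``(w_cds, z_cds)``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    codons = split_codons(z_cds.upper())
    for i, c in enumerate(codons):
        if is_stop(c):
            raise ValueError(f"internal stop codon {c} at codon {i}")
    if not 0 <= omega:
        raise ValueError("omega must be non-negative")
    target = int(round(expected_subs_per_codon * len(codons)))
    if target == 0:
        return "".join(codons), z_cds.upper()

    accepted = 0
    attempts = 0
    max_attempts = 1000 * target + 10000
    L = 3 * len(codons)
    while accepted < target:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                "substitution target unreachable (omega too small for the "
                "requested divergence?)"
            )
        pos = int(rng.integers(0, L))
        ci, off = divmod(pos, 3)
        old = codons[ci]
        nt = NUCLEOTIDES[int(rng.integers(0, 4))]
        if nt == old[off]:
            continue
        new = old[:off] + nt + old[off + 1 :]
        if is_stop(new):
            continue
        if CODON_TO_AA[new] != CODON_TO_AA[old]:
            if rng.random() >= omega:
                continue
        codons[ci] = new
        accepted += 1
    return "".join(codons), z_cds.upper()


def fragmentize(
    transcript: str,
    n_fragments: int,
    min_overlap: int = 60,
    orphan_prob: float = 0.0,
    seed: int | np.random.Generator = 0,
    id_prefix: str = "frag",
) -> tuple[list[Fragment], pd.DataFrame]:
    """Split a transcript into tiling, partially overlapping fragments.

    Adjacent fragments overlap by at least ``min_overlap`` bases except that
    each junction independently becomes a gap with probability
    ``orphan_prob``.  A random subset of fragments is reverse-complemented,
    and each fragment is assigned a fake evidence source and a pseudo-
    chromosome, emulating transcript pieces scattered across an unfinished
    genome assembly.

    Returns the fragments plus a truth table with the true interval, strand
    and source of every fragment on the input transcript.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L = len(transcript)
    if n_fragments < 1:
        raise ValueError("n_fragments must be >= 1")
    if n_fragments * min_overlap >= L:
        raise ValueError(
            f"n_fragments ({n_fragments}) x min_overlap ({min_overlap}) "
            f"exceeds transcript length ({L})"
        )

    cuts = [round(i * L / n_fragments) for i in range(n_fragments + 1)]
    starts = [0] * n_fragments
    ends = [0] * n_fragments
    ends[-1] = L
    seg = L / n_fragments
    max_ov = max(min_overlap + 1, min(int(2 * min_overlap), int(seg // 2)))
    for j in range(1, n_fragments):
        c = cuts[j]
        if rng.random() < orphan_prob:
            g = int(rng.integers(5, max(6, min(50, int(seg // 4)))))
            ends[j - 1] = max(starts[j - 1] + 1, c - g // 2)
            starts[j] = min(L - 1, c + g - g // 2)
        else:
            ov = int(rng.integers(min_overlap, max_ov + 1))
            ends[j - 1] = min(L, c + (ov + 1) // 2)
            starts[j] = max(0, c - ov // 2)

    fragments: list[Fragment] = []
    rows = []
    chroms = ("W_random", "Un_random", "autosome")
    for i in range(n_fragments):
        s, e = starts[i], ends[i]
        sub = transcript[s:e]
        strand = "+" if rng.random() < 0.5 else "-"
        seq = sub if strand == "+" else revcomp(sub)
        source = FRAGMENT_SOURCES[int(rng.integers(0, len(FRAGMENT_SOURCES)))]
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        fid = f"{id_prefix}_{i:02d}"
        fragments.append(Fragment(id=fid, sequence=seq, source=source, chrom=chrom))
        rows.append(
            {"fragment_id": fid, "start": s, "end": e, "strand": strand,
             "source": source, "chrom": chrom}
        )
    return fragments, pd.DataFrame(rows).set_index("fragment_id")


# ---------------------------------------------------------------------------
# retroviral decoys
# ---------------------------------------------------------------------------

_NO_A = ("C", "G", "T")  # UTR alphabet: no A => no ATG, no stop codons


def _utr(rng: np.random.Generator, lo: int = 30, hi: int = 80) -> str:
    n = int(rng.integers(lo, hi + 1))
    return "".join(_NO_A[int(i)] for i in rng.integers(0, 3, size=n))


def make_retroviral_decoys(
    n: int,
    protein_panel: Sequence[tuple[str, str]],
    seed: int | np.random.Generator = 0,
    noise: float = 0.1,
) -> list[Fragment]:
    """Transcripts carrying an ORF back-translated from a retroviral protein.

    Each decoy is 5'UTR + ATG...ORF...stop + 3'UTR, the ORF back-translated
    from a randomly chosen panel protein with up to ``noise`` of its codons
    replaced by random sense codons.  UTRs contain no adenine, so the
    back-translated ORF is exactly the maximal ORF of the transcript.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if not protein_panel:
        raise ValueError("protein panel is empty")
    if not 0 <= noise <= 1:
        raise ValueError("noise must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    decoys = []
    for i in range(n):
        pid, prot = protein_panel[int(rng.integers(0, len(protein_panel)))]
        codons = []
        for j, aa in enumerate(prot):
            if aa not in AA_TO_CODONS:
                raise ValueError(f"panel protein {pid} has invalid residue {aa!r}")
            if j > 0 and rng.random() < noise:
                codons.append(SENSE_CODONS[int(rng.integers(0, len(SENSE_CODONS)))])
            else:
                opts = AA_TO_CODONS[aa]
                codons.append(opts[int(rng.integers(0, len(opts)))])
        seq = _utr(rng) + "".join(codons) + "TAA" + _utr(rng)
        decoys.append(
            Fragment(id=f"retro_decoy_{i:02d}", sequence=seq, source="genome-guided",
                     chrom="W_random")
        )
    return decoys


# ---------------------------------------------------------------------------
# candidate pool for the discovery stage
# ---------------------------------------------------------------------------


def build_candidate_pool(
    experiment: CountExperiment,
    truth: SimTruth,
    protein_panel: Sequence[tuple[str, str]],
    seed: int | np.random.Generator = 0,
    n_decoys: int = 8,
    n_background: int = 60,
) -> tuple[list[Fragment], pd.DataFrame, pd.DataFrame]:
    """Assemble the transcript pool the W-discovery stage screens.

    Pool = all true W/W_random transcripts from ``experiment`` + a sample of
    autosomal and Z background transcripts + retroviral decoys with
    female-restricted expression.  Returns ``(candidates, fpkm, truth)``
    where ``fpkm`` is candidates × samples and ``truth`` flags each
    candidate as ``w`` / ``background`` / ``decoy``.
    """
    from .dimorphism import compute_fpkm, normalize_library_sizes

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eff = normalize_library_sizes(experiment)
    fpkm_all = compute_fpkm(
        experiment.counts, experiment.annotation["length"], eff
    )

    ann = experiment.annotation
    w_ids = list(ann.index[ann["chrom_class"].isin(W_CLASSES)])
    bg_pool = list(ann.index[~ann["chrom_class"].isin(W_CLASSES)])
    bg_ids = [bg_pool[i] for i in rng.permutation(len(bg_pool))[:n_background]]

    candidates: list[Fragment] = []
    rows = []
    fpkm_rows = {}
    for gid in w_ids + bg_ids:
        n_codons = max(40, int(ann.loc[gid, "length"]) // 3)
        seq = random_cds(min(n_codons, 600), rng)
        kind = "w" if gid in set(w_ids) else "background"
        candidates.append(
            Fragment(
                id=gid,
                sequence=seq,
                source="annotation",
                chrom=str(ann.loc[gid, "chrom_class"])
                if ann.loc[gid, "chrom_class"] in ("W_random", "Un_random", "autosome")
                else "autosome",
            )
        )
        rows.append({"candidate_id": gid, "kind": kind})
        fpkm_rows[gid] = fpkm_all.loc[gid]

    decoys = make_retroviral_decoys(n_decoys, protein_panel, rng)
    female = experiment.samples(sex="F")
    for d in decoys:
        candidates.append(d)
        rows.append({"candidate_id": d.id, "kind": "decoy"})
        row = pd.Series(0.0, index=fpkm_all.columns)
        row[female] = float(np.exp(rng.uniform(math.log(5.0), math.log(100.0))))
        fpkm_rows[d.id] = row

    fpkm = pd.DataFrame(fpkm_rows).T.reindex([c.id for c in candidates])
    fpkm.index.name = "candidate_id"
    truth_df = pd.DataFrame(rows).set_index("candidate_id")
    return candidates, fpkm, truth_df
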