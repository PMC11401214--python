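"""Synthetic camelid VHH repertoires with full ground truth.

The generator emulates the inputs of a serum-proteomics nanobody
discovery experiment: a clonal VHH repertoire built from a conserved
framework scaffold with variable CDR loops, single-step PCR amplicons
carrying the leader forward-primer site and long-/short-hinge reverse
primer sites, overlapping 2x300-class paired-end reads with
substitution errors, and noisy dual-protease (trypsin + chymotrypsin)
peptide observations for a small set of "binder" clones, plus a decoy
peptide set from an unrelated-antigen pulldown for the cross-antigen
filter. Every stochastic step flows through one seeded generator, so a
given seed reproduces outputs exactly.

Clone abundances follow a log-normal law, creating the regime in which
read counts separate bona fide transcripts from PCR/sequencing-error
variants; binders are drawn with probability proportional to abundance,
since serum antibodies captured by affinity purification come from
expanded, well-represented clones.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .amplicon import Hinge, PrimerDef, reverse_complement
from .digest import EXPASY_RULES, digest
from .seqio import PeptideObservation, SequenceRecord

# ---------------------------------------------------------------------------
# The printed primers of the single-step VHH amplification design.

CALL001 = PrimerDef(
    name="6N-CALL001b",
    annealing_seq="GTCCTGGCTGCTCTTYTACAAGG",
    orientation="forward",
    tail_len=6,
)
LH_REV = PrimerDef(
    name="6N-LH-rev",
    annealing_seq="GTGGTTGTGGTTTTGGTGTCTTGGG",
    orientation="reverse",
    tail_len=6,
    hinge=Hinge.LONG_IGG2,
)
SH_REV = PrimerDef(
    name="6N-SH-rev",
    annealing_seq="CTGGGGTCTTCGCTGTGGTGC",
    orientation="reverse",
    tail_len=6,
    hinge=Hinge.SHORT_IGG3,
)
DEFAULT_FWD_PRIMERS = (CALL001,)
DEFAULT_REV_PRIMERS = (LH_REV, SH_REV)

# ---------------------------------------------------------------------------
# Default framework scaffold. Anchor landmarks: Cys at FR1 index 22,
# Trp at FR2 index 2, Cys at FR3 index 38 (Y-Y-C end), FR4 starting W-G-Q-G.

FR1 = "QVQLVESGGGGLVQAGGSLRLSCAAS"   # 26 residues
FR2 = "MAWFRQAPGKEREFVSG"            # 17 residues, VHH-type hallmark
FR2_GLEW = "MAWFRQAPGKGLEWVSG"       # conventional-VH hallmark at IMGT 49-52
FR3 = "SEYADSVKGRFTISRDNAKNTMYLQMNSLKPEDTAMYYC"  # 39 residues
FR4 = "WGQGTQVTVSS"                  # 11 residues
HINGE_STUB = {Hinge.LONG_IGG2: "EP", Hinge.SHORT_IGG3: "AH"}

#: CDR residue alphabet: the 18 standard residues minus Cys and Trp, which
#: are reserved as framework anchor landmarks.
CDR_ALPHABET = "ADEFGHIKLMNPQRSTVY"

_CODONS = {
    "A": ("GCT", "GCC", "GCA", "GCG"), "C": ("TGT", "TGC"),
    "D": ("GAT", "GAC"), "E": ("GAA", "GAG"), "F": ("TTT", "TTC"),
    "G": ("GGT", "GGC", "GGA", "GGG"), "H": ("CAT", "CAC"),
    "I": ("ATT", "ATC", "ATA"), "K": ("AAA", "AAG"),
    "L": ("TTA", "TTG", "CTT", "CTC", "CTA", "CTG"),
    "M": ("ATG",), "N": ("AAT", "AAC"), "P": ("CCT", "CCC", "CCA", "CCG"),
    "Q": ("CAA", "CAG"), "R": ("CGT", "CGC", "CGA", "CGG", "AGA", "AGG"),
    "S": ("TCT", "TCC", "TCA", "TCG", "AGT", "AGC"),
    "T": ("ACT", "ACC", "ACA", "ACG"), "V": ("GTT", "GTC", "GTA", "GTG"),
    "W": ("TGG",), "Y": ("TAT", "TAC"),
}


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic experiment.

    Defaults reflect a desk-scale rendition of the real workflow:
    500 clones, log-normal abundances, 20k overlapping 2x300 read pairs
    at 0.3% per-base substitution error, 5 binder clones with 60%
    per-peptide detection probability, and a 5% contaminant rate.
    """

    n_clones: int = 500
    n_binders: int = 5
    n_read_pairs: int = 20_000
    read_len: int = 300
    error_rate: float = 0.003
    detection_prob: float = 0.6
    contaminant_rate: float = 0.05
    cdr1_len: tuple[int, int] = (6, 10)
    cdr2_len: tuple[int, int] = (5, 9)
    cdr3_len: tuple[int, int] = (5, 22)
    abundance_sigma: float = 1.0
    min_peptide_len: int = 6
    obs_missed_cleavages: int = 2  # incomplete digestion in the observed lists
    glew_fraction: float = 0.0  # fraction of clones given the VH hallmark FR2
    seed: int = 0

    def __post_init__(self):
        for p in (self.error_rate, self.detection_prob, self.contaminant_rate, self.glew_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.n_clones < 1:
            raise ValueError("n_clones must be >= 1")
        if not 0 <= self.n_binders <= self.n_clones:
            raise ValueError("n_binders must be in [0, n_clones]")


@dataclasses.dataclass(frozen=True)
class SimClone:
    id: str
    protein: str
    dna: str          # coding DNA, translate(dna) == protein
    amplicon: str     # fwd primer site + coding DNA + rc(reverse primer site)
    abundance: float
    hinge: Hinge
    regions: dict     # true region boundaries, 0-based half-open
    cdr3: str
    has_glew: bool


@dataclasses.dataclass(frozen=True)
class GroundTruth:
    clones: tuple[SimClone, ...]
    binder_ids: tuple[str, ...]
    decoy_binder_ids: tuple[str, ...]
    peptide_provenance: dict  # peptide -> set of clone ids (non-contaminants)

    def clone(self, cid: str) -> SimClone:
        return next(c for c in self.clones if c.id == cid)


def _rng(stage: int, seed: int) -> np.random.Generator:
    return np.random.default_rng([stage, seed])


def _draw_cdr(rng, length_range) -> str:
    n = int(rng.integers(length_range[0], length_range[1] + 1))
    return "".join(rng.choice(list(CDR_ALPHABET), size=n))


def _reverse_translate(protein: str, rng) -> str:
    return "".join(
        _CODONS[aa][int(rng.integers(len(_CODONS[aa])))] for aa in protein
    )


def simulate_repertoire(cfg: SimConfig) -> GroundTruth:
    """Generate the clonal repertoire with true annotations and abundances."""
    rng = _rng(1, cfg.seed)
    clones = []
    seen = set()
    n_glew = int(round(cfg.glew_fraction * cfg.n_clones))
    for i in range(cfg.n_clones):
        while True:
            cdr1 = _draw_cdr(rng, cfg.cdr1_len)
            cdr2 = _draw_cdr(rng, cfg.cdr2_len)
            cdr3 = _draw_cdr(rng, cfg.cdr3_len)
            has_glew = i < n_glew
            fr2 = FR2_GLEW if has_glew else FR2
            hinge = Hinge.LONG_IGG2 if rng.random() < 0.5 else Hinge.SHORT_IGG3
            protein = FR1 + cdr1 + fr2 + cdr2 + FR3 + cdr3 + FR4 + HINGE_STUB[hinge]
            if protein not in seen:
                seen.add(protein)
                break
        b = [0, len(FR1)]
        for seg in (cdr1, fr2, cdr2, FR3, cdr3, FR4 + HINGE_STUB[hinge]):
            b.append(b[-1] + len(seg))
        regions = {
            "FR1": (b[0], b[1]), "CDR1": (b[1], b[2]), "FR2": (b[2], b[3]),
            "CDR2": (b[3], b[4]), "FR3": (b[4], b[5]), "CDR3": (b[5], b[6]),
            "FR4": (b[6], b[7]),
        }
        dna = _reverse_translate(protein, rng)
        fwd_site = CALL001.annealing_seq.replace("Y", "C" if rng.random() < 0.5 else "T")
        rev = LH_REV if hinge == Hinge.LONG_IGG2 else SH_REV
        amplicon = fwd_site + dna + reverse_complement(rev.annealing_seq)
        clones.append(
            SimClone(
                id=f"clone{i:04d}", protein=protein, dna=dna, amplicon=amplicon,
                abundance=0.0, hinge=hinge, regions=regions, cdr3=cdr3,
                has_glew=has_glew,
            )
        )
    raw = rng.lognormal(mean=0.0, sigma=cfg.abundance_sigma, size=cfg.n_clones)
    total = raw.sum()
    clones = [
        dataclasses.replace(c, abundance=float(a / total))
        for c, a in zip(clones, raw)
    ]
    abundances = np.array([c.abundance for c in clones])
    # binders (and a disjoint decoy binder set) drawn proportional to abundance
    n_pick = min(2 * cfg.n_binders, cfg.n_clones)
    picked = (
        rng.choice(cfg.n_clones, size=n_pick, replace=False, p=abundances)
        if n_pick
        else np.array([], dtype=int)
    )
    binders = tuple(clones[i].id for i in picked[: cfg.n_binders])
    decoys = tuple(clones[i].id for i in picked[cfg.n_binders: 2 * cfg.n_binders])
    return GroundTruth(
        clones=tuple(clones), binder_ids=binders, decoy_binder_ids=decoys,
        peptide_provenance={},
    )


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_B2I = np.zeros(128, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _B2I[_b] = _i


def _phred_for(error_rate: float) -> int:
    if error_rate <= 0:
        return 40
    return min(40, int(round(-10.0 * math.log10(error_rate))))


def simulate_reads(truth: GroundTruth, cfg: SimConfig) -> list[tuple[SequenceRecord, SequenceRecord]]:
    """Draw overlapping paired-end reads from the clone amplicons.

    Each sequenced molecule is the clone amplicon flanked by fresh
    random 6N tails (the primer diversity bases). Reads are the first
    and last ``read_len`` bases (R2 reverse-complemented) with i.i.d.
    substitution errors at ``error_rate`` and qualities set to the
    Phred equivalent of that error rate.
    """
    rng = _rng(2, cfg.seed)
    min_len = min(len(c.amplicon) for c in truth.clones) + 12
    if cfg.read_len > min_len:
        raise ValueError(
            f"read_len {cfg.read_len} exceeds shortest amplicon length {min_len}"
        )
    p = np.array([c.abundance for c in truth.clones])
    counts = rng.multinomial(cfg.n_read_pairs, p / p.sum())
    q = _phred_for(cfg.error_rate)
    pairs = []
    read_no = 0
    for clone, n_reads in zip(truth.clones, counts):
        if n_reads == 0:
            continue
        core = _B2I[np.frombuffer(clone.amplicon.encode(), dtype=np.uint8)]
        total = len(core) + 12
        mol = np.empty((n_reads, total), dtype=np.uint8)
        mol[:, 6:-6] = core
        mol[:, :6] = rng.integers(0, 4, size=(n_reads, 6))
        mol[:, -6:] = rng.integers(0, 4, size=(n_reads, 6))
        if cfg.error_rate > 0:
            err = rng.random(mol.shape) < cfg.error_rate
            shift = rng.integers(1, 4, size=int(err.sum()))
            mol[err] = (mol[err] + shift) % 4
        rl = min(cfg.read_len, total)
        qual = (q,) * rl
        for row in mol:
            seq = _BASES[row].tobytes().decode()
            r1 = seq[:rl]
            r2 = reverse_complement(seq[-rl:])
            rid = f"r{read_no:06d}:{clone.id}"
            pairs.append(
                (
                    SequenceRecord(id=rid, seq=r1, qual=qual),
                    SequenceRecord(id=rid, seq=r2, qual=qual),
                )
            )
            read_no += 1
    return pairs


def simulate_peptides(
    truth: GroundTruth, cfg: SimConfig
) -> tuple[list[PeptideObservation], list[PeptideObservation], GroundTruth]:
    """Generate noisy dual-protease peptide observations for the binders.

    Binder proteins are digested in silico with trypsin and with
    chymotrypsin; chymotryptic peptides are emitted under both the
    high- and low-specificity rules, mirroring how chymotryptic MS data
    are searched. Enzymatic digestion of real samples is incomplete, so
    the observable pool includes peptides with up to
    ``obs_missed_cleavages`` missed sites; each distinct peptide of at
    least ``min_peptide_len`` residues is then observed with probability
    ``detection_prob``. Contaminant
    peptides are added at ``contaminant_rate``: half drawn from random
    non-binder clones, half random strings. Clone-derived contaminants
    model nonspecifically co-purifying VHH background, which sticks to
    any affinity resin — so those peptides are placed in the
    unrelated-antigen (decoy) observation set as well, where the
    cross-antigen filter can see them; random-string contaminants stay
    sample-specific. The decoy set itself is built from the disjoint
    decoy binder set, emulating a pulldown against an unrelated antigen.
    Returns (observations, decoy observations, truth with provenance).
    """
    rng = _rng(3, cfg.seed)
    provenance: dict[str, set] = {}

    def digest_observations(clone_ids, sample_id, record_provenance):
        obs = []
        for cid in clone_ids:
            clone = truth.clone(cid)
            for protease in ("trypsin", "chymotrypsin_high", "chymotrypsin_low"):
                result = digest(
                    clone.protein, EXPASY_RULES[protease],
                    missed_cleavages=cfg.obs_missed_cleavages,
                )
                for pep in sorted({
                    p.peptide for p in result.peptides
                    if len(p.peptide) >= cfg.min_peptide_len
                }):
                    if record_provenance:
                        provenance.setdefault(pep, set()).add(cid)
                    if rng.random() < cfg.detection_prob:
                        obs.append(
                            PeptideObservation(
                                peptide=pep, protease=protease,
                                sample_id=sample_id,
                            )
                        )
        return obs

    observations = digest_observations(truth.binder_ids, "target", True)
    decoy_obs = digest_observations(truth.decoy_binder_ids, "unrelated", False)
    n_contam = int(rng.poisson(cfg.contaminant_rate * max(len(observations), 1)))
    non_binders = [
        c for c in truth.clones
        if c.id not in truth.binder_ids and c.id not in truth.decoy_binder_ids
    ]
    for _ in range(n_contam):
        protease = "trypsin" if rng.random() < 0.5 else "chymotrypsin_high"
        if non_binders and rng.random() < 0.5:
            clone = non_binders[int(rng.integers(len(non_binders)))]
            peps = [
                p.peptide
                for p in digest(clone.protein, EXPASY_RULES[protease]).peptides
                if len(p.peptide) >= cfg.min_peptide_len
            ]
            if not peps:
                continue
            pep = peps[int(rng.integers(len(peps)))]
            provenance.setdefault(pep, set()).add(clone.id)
            # nonspecific background co-purifies in every pulldown
            decoy_obs.append(
                PeptideObservation(peptide=pep, protease=protease, sample_id="unrelated")
            )
        else:
            n = int(rng.integers(8, 16))
            pep = "".join(rng.choice(list(CDR_ALPHABET), size=n))
        observations.append(
            PeptideObservation(peptide=pep, protease=protease, sample_id="target")
        )
    truth_with_prov = dataclasses.replace(truth, peptide_provenance=provenance)
    return observations, decoy_obs, truth_with_prov
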