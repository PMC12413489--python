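"""Synthetic MALDI and LC-ESI cohorts with known planted structure.

Every mining stage in this package is validated against data whose ground
truth is known by construction.  The generator emulates the study design the
miners assume:

* MALDI: per species x processing state, 27 centroid spectra (3 individuals
  x 3 technical replicates x 3 target spots), each with 80-110 peaks in the
  900-4500 m/z window — shared background peaks present in every spectrum of
  every species, cohort-exclusive planted peaks subject to detection
  dropout, uniform filler peaks, and Gaussian m/z jitter on everything.
* LC-ESI: per species x state, 9 peptide tables (3 individuals x 3
  technical replicates) drawn from in-silico tryptic digests (one missed
  cleavage, peptide length 7-30) of synthetic proteomes with per-sample
  detection dropout and random methionine oxidation.  Proteomes mix
  species-unique proteins, proteins shared verbatim across species
  (conserved background) and state-specific proteins (emulating
  thermostable proteins that surface mainly in cooked meat).

Truth tables are first-class outputs so tests never reach into generator
internals.  All randomness flows from a single seeded generator: a fixed
seed reproduces the output bit for bit.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .io_meta import (
    PeakList,
    PeptideObservation,
    SampleKey,
    write_manifest,
    write_peaklist,
    write_peptide_table,
)
from .masscalc import RESIDUE_MASSES, digest_trypsin

__all__ = [
    "SyntheticConfig",
    "SyntheticProtein",
    "maldi_cohort_keys",
    "lcesi_cohort_keys",
    "make_proteomes",
    "simulate_maldi_cohort",
    "simulate_lcesi_cohort",
    "write_simulation",
]

_ALPHABET = sorted(RESIDUE_MASSES)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design parameters of the synthetic cohorts.

    Defaults mirror the design the miners assume: 6 species, raw and cooked
    states, 27 MALDI spectra and 9 peptide tables per cohort, 3 planted
    exclusive peaks per cohort over >= 5 shared background peaks, 95 %
    per-spectrum detection, 0.03 Da m/z jitter, peaks in the 900-4500 Da
    acquisition window.
    """

    seed: int
    species: tuple[str, ...] = ("carp", "mackerel", "pike", "pollock", "salmon", "trout")
    states: tuple[str, ...] = ("raw", "cooked")
    individuals: int = 3
    technical_replicates: int = 3
    spots: int = 3
    # MALDI
    n_planted_exclusive: int = 3  # per species x state cohort
    n_shared_background: int = 8
    detection_prob: float = 0.95
    mz_jitter_sd: float = 0.03
    peaks_per_spectrum: tuple[int, int] = (80, 110)
    mass_range: tuple[float, float] = (900.0, 4500.0)
    min_separation: float = 0.5  # between planted/background positions, Da
    # proteome / LC-ESI
    n_core_proteins: int = 4  # species-unique, present in both states
    n_shared_proteins: int = 2  # identical across species
    n_state_proteins: int = 1  # per state, species-unique and state-exclusive
    protein_length: tuple[int, int] = (150, 300)
    kr_frequency: float = 0.10  # combined K+R frequency -> tryptic peptides mostly 7-30
    peptide_detection_prob: float = 0.95
    oxidation_prob: float = 0.2

    def __post_init__(self) -> None:
        for name in ("detection_prob", "peptide_detection_prob", "oxidation_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.mass_range
        if not (0 < lo < hi):
            raise ValueError("mass_range must be positive and ordered")
        if self.peaks_per_spectrum[0] > self.peaks_per_spectrum[1]:
            raise ValueError("peaks_per_spectrum range must be ordered")

    @property
    def n_maldi_per_cohort(self) -> int:
        return self.individuals * self.technical_replicates * self.spots

    @property
    def n_lcesi_per_cohort(self) -> int:
        return self.individuals * self.technical_replicates


@dataclass(frozen=True)
class SyntheticProtein:
    accession: str
    name: str
    sequence: str
    role: str  # "core" | "shared" | "raw_only" | "cooked_only"


def maldi_cohort_keys(cfg: SyntheticConfig, species: str, state: str) -> list[SampleKey]:
    return [
        SampleKey(species, state, i, r, s)
        for i in range(1, cfg.individuals + 1)
        for r in range(1, cfg.technical_replicates + 1)
        for s in range(1, cfg.spots + 1)
    ]


def lcesi_cohort_keys(cfg: SyntheticConfig, species: str, state: str) -> list[SampleKey]:
    return [
        SampleKey(species, state, i, r, None)
        for i in range(1, cfg.individuals + 1)
        for r in range(1, cfg.technical_replicates + 1)
    ]


# ---------------------------------------------------------------------------
# proteomes

def _random_protein(rng: np.random.Generator, cfg: SyntheticConfig) -> str:
    length = int(rng.integers(cfg.protein_length[0], cfg.protein_length[1] + 1))
    others = [a for a in _ALPHABET if a not in "KR"]
    p_other = (1.0 - cfg.kr_frequency) / len(others)
    letters = others + ["K", "R"]
    probs = [p_other] * len(others) + [cfg.kr_frequency / 2] * 2
    return "".join(rng.choice(letters, size=length, p=probs))


def make_proteomes(
    cfg: SyntheticConfig, rng: Optional[np.random.Generator] = None
) -> dict[str, list[SyntheticProtein]]:
    """Per-species synthetic proteomes with planted structure.

    Each species receives ``n_core_proteins`` unique proteins active in both
    states, ``n_state_proteins`` per state active only in that state, and
    ``n_shared_proteins`` conserved proteins identical across every species.
    Species-unique random sequences make their tryptic peptides
    species-characteristic by construction.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    shared = [
        SyntheticProtein(
            accession=f"SHARED{j:03d}",
            name=f"conserved muscle protein {j + 1}",
            sequence=_random_protein(rng, cfg),
            role="shared",
        )
        for j in range(cfg.n_shared_proteins)
    ]
    proteomes: dict[str, list[SyntheticProtein]] = {}
    for sp in cfg.species:
        prots = list(shared)
        for j in range(cfg.n_core_proteins):
            prots.append(
                SyntheticProtein(
                    accession=f"{sp.upper()[:3]}C{j:03d}",
                    name=f"{sp} muscle protein {j + 1}",
                    sequence=_random_protein(rng, cfg),
                    role="core",
                )
            )
        for state in cfg.states:
            for j in range(cfg.n_state_proteins):
                prots.append(
                    SyntheticProtein(
                        accession=f"{sp.upper()[:3]}{state[0].upper()}{j:03d}",
                        name=f"{sp} {state}-enriched protein {j + 1}",
                        sequence=_random_protein(rng, cfg),
                        role=f"{state}_only",
                    )
                )
        proteomes[sp] = prots
    return proteomes


def _active_proteins(
    proteome: Sequence[SyntheticProtein], state: str
) -> list[SyntheticProtein]:
    return [p for p in proteome if p.role in ("core", "shared", f"{state}_only")]


def _digest_with_flanks(seq: str) -> list[tuple[str, str, str]]:
    """(n_flank, peptide, c_flank) for every <=1-missed-cleavage fragment."""
    out = []
    for pep in digest_trypsin(seq, max_missed=1, min_len=7, max_len=30):
        start = seq.find(pep)
        n_flank = "-" if start == 0 else seq[start - 1]
        end = start + len(pep)
        c_flank = "-" if end == len(seq) else seq[end]
        out.append((n_flank, pep, c_flank))
    return out


def cohort_peptide_pools(
    cfg: SyntheticConfig, proteomes: dict[str, list[SyntheticProtein]]
) -> dict[tuple[str, str], dict[str, list[SyntheticProtein]]]:
    """For every (species, state) cohort: peptide -> contributing proteins."""
    pools: dict[tuple[str, str], dict[str, list[SyntheticProtein]]] = {}
    digest_cache: dict[str, list[tuple[str, str, str]]] = {}
    for sp in proteomes:
        for state in cfg.states:
            pool: dict[str, list[SyntheticProtein]] = {}
            for prot in _active_proteins(proteomes[sp], state):
                if prot.sequence not in digest_cache:
                    digest_cache[prot.sequence] = _digest_with_flanks(prot.sequence)
                for _n, pep, _c in digest_cache[prot.sequence]:
                    pool.setdefault(pep, []).append(prot)
            pools[(sp, state)] = pool
    return pools


def characteristic_truth(
    pools: dict[tuple[str, str], dict[str, list[SyntheticProtein]]],
    target: tuple[str, str],
    others: Sequence[tuple[str, str]],
) -> frozenset[str]:
    """Peptides available to the target cohort and to none of the others."""
    other_union: set[str] = set()
    for o in others:
        other_union |= set(pools[o])
    return frozenset(set(pools[target]) - other_union)


# ---------------------------------------------------------------------------
# MALDI simulation

def _sample_separated(
    rng: np.random.Generator, n: int, lo: float, hi: float, min_sep: float
) -> np.ndarray:
    """n positions in [lo, hi], pairwise separated by at least min_sep."""
    out: list[float] = []
    attempts = 0
    while len(out) < n:
        cand = float(rng.uniform(lo, hi))
        if all(abs(cand - x) >= min_sep for x in out):
            out.append(cand)
        attempts += 1
        if attempts > 1000 * n:
            raise RuntimeError("could not place separated positions; widen mass_range")
    return np.asarray(out)


def simulate_maldi_cohort(
    cfg: SyntheticConfig,
    states: Optional[Sequence[str]] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[PeakList], dict[tuple[str, str], tuple[float, ...]]]:
    """Simulate MALDI peak-list cohorts for every species x state.

    Returns the spectra and a truth table mapping each cohort to its planted
    exclusive m/z positions (unjittered).  Shared background peaks appear in
    every spectrum; planted peaks are subject to per-spectrum detection
    dropout; filler peaks are uniform over the acquisition window; every
    emitted m/z carries Gaussian jitter.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    states = tuple(cfg.states if states is None else states)
    cohorts = [(sp, st) for sp in cfg.species for st in states]
    n_special = len(cohorts) * cfg.n_planted_exclusive + cfg.n_shared_background
    lo, hi = cfg.mass_range
    positions = _sample_separated(rng, n_special, lo + 5, hi - 5, cfg.min_separation)
    background = positions[: cfg.n_shared_background]
    truth: dict[tuple[str, str], tuple[float, ...]] = {}
    off = cfg.n_shared_background
    for cohort in cohorts:
        truth[cohort] = tuple(
            sorted(positions[off : off + cfg.n_planted_exclusive])
        )
        off += cfg.n_planted_exclusive

    spectra: list[PeakList] = []
    for sp, st in cohorts:
        planted = np.asarray(truth[(sp, st)])
        for key in maldi_cohort_keys(cfg, sp, st):
            mzs = list(background)
            detected = rng.random(planted.size) < cfg.detection_prob
            mzs.extend(planted[detected])
            n_target = int(
                rng.integers(cfg.peaks_per_spectrum[0], cfg.peaks_per_spectrum[1] + 1)
            )
            n_filler = max(0, n_target - len(mzs))
            mzs.extend(rng.uniform(lo, hi, size=n_filler))
            mzs = np.asarray(mzs) + rng.normal(0.0, cfg.mz_jitter_sd, size=len(mzs))
            intensities = rng.exponential(scale=100.0, size=len(mzs))
            spectra.append(PeakList.from_pairs(key, zip(mzs, intensities)))
    return spectra, truth


# ---------------------------------------------------------------------------
# LC-ESI simulation

def simulate_lcesi_cohort(
    cfg: SyntheticConfig,
    proteomes: Optional[dict[str, list[SyntheticProtein]]] = None,
    species: Optional[Sequence[str]] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[
    dict[SampleKey, list[PeptideObservation]],
    dict[str, dict[tuple[str, str], frozenset[str]]],
]:
    """Simulate per-sample peptide tables plus exact characteristic truth.

    Returns ``(observations_by_sample, truth)`` where truth has two entries:
    ``"species"`` — per cohort, peptides characteristic versus the *other
    species in the same state*; ``"four_way"`` — per cohort, peptides
    characteristic versus *every* other cohort (species and state).  Truth is
    computed from the designed peptide pools by exact set logic, before any
    stochastic dropout.
    """
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    if proteomes is None:
        proteomes = make_proteomes(cfg, rng)
    species = tuple(proteomes if species is None else species)
    pools = cohort_peptide_pools(cfg, {sp: proteomes[sp] for sp in species})
    cohorts = [(sp, st) for sp in species for st in cfg.states]

    truth = {
        "species": {
            (sp, st): characteristic_truth(
                pools, (sp, st), [(o, st) for o in species if o != sp]
            )
            for sp, st in cohorts
        },
        "four_way": {
            c: characteristic_truth(pools, c, [o for o in cohorts if o != c])
            for c in cohorts
        },
    }

    flank_cache: dict[str, dict[str, tuple[str, str]]] = {}
    for sp in species:
        for prot in proteomes[sp]:
            if prot.sequence not in flank_cache:
                flank_cache[prot.sequence] = {
                    pep: (n, c) for n, pep, c in _digest_with_flanks(prot.sequence)
                }

    observations: dict[SampleKey, list[PeptideObservation]] = {}
    for sp, st in cohorts:
        pool = pools[(sp, st)]
        peps = sorted(pool)
        for key in lcesi_cohort_keys(cfg, sp, st):
            obs_list: list[PeptideObservation] = []
            detected = rng.random(len(peps)) < cfg.peptide_detection_prob
            oxid = rng.random(len(peps)) < cfg.oxidation_prob
            for pep, det, ox in zip(peps, detected, oxid):
                if not det:
                    continue
                for prot in pool[pep]:
                    n_flank, c_flank = flank_cache[prot.sequence][pep]
                    mods: tuple = ()
                    if ox and "M" in pep:
                        mods = ((pep.index("M") + 1, "Oxidation", 15.994915),)
                    obs_list.append(
                        PeptideObservation(
                            key=key,
                            core_sequence=pep,
                            n_flank=n_flank,
                            c_flank=c_flank,
                            modifications=mods,
                            protein_accession=prot.accession,
                            protein_name=prot.name,
                        )
                    )
            observations[key] = obs_list
    return observations, truth


# ---------------------------------------------------------------------------
# file-level output

def write_simulation(cfg: SyntheticConfig, outdir) -> Path:
    """Write a complete simulated study to ``outdir``.

    Produces ``manifest.csv`` covering peak lists and peptide tables,
    per-spectrum peak-list CSVs, per-sample peptide-table CSVs, and truth
    TSVs (``truth_maldi.tsv``, ``truth_sequences.tsv``).  Deterministic for a
    fixed config.  Returns the manifest path.
    """
    outdir = Path(outdir)
    (outdir / "peaklists").mkdir(parents=True, exist_ok=True)
    (outdir / "peptides").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    spectra, maldi_truth = simulate_maldi_cohort(cfg, rng=rng)
    proteomes = make_proteomes(cfg, rng)
    observations, seq_truth = simulate_lcesi_cohort(cfg, proteomes, rng=rng)

    entries = []
    for pl in spectra:
        k = pl.key
        rel = Path("peaklists") / (
            f"{k.species}_{k.state}_i{k.individual}_r{k.technical_replicate}_s{k.spot}.csv"
        )
        write_peaklist(pl, outdir / rel)
        entries.append((rel, k))
    for key in sorted(observations):
        rel = Path("peptides") / (
            f"{key.species}_{key.state}_i{key.individual}_r{key.technical_replicate}.csv"
        )
        write_peptide_table(observations[key], outdir / rel)
        entries.append((rel, key))
    manifest = outdir / "manifest.csv"
    write_manifest(entries, manifest)

    with open(outdir / "truth_maldi.tsv", "w") as fh:
        fh.write("species\tstate\tmz\n")
        for (sp, st), mzs in sorted(maldi_truth.items()):
            for mz in mzs:
                fh.write(f"{sp}\t{st}\t{mz:.4f}\n")
    with open(outdir / "truth_sequences.tsv", "w") as fh:
        fh.write("comparison\tspecies\tstate\tsequence\n")
        for comparison in ("species", "four_way"):
            for (sp, st), seqs in sorted(seq_truth[comparison].items()):
                for s in sorted(seqs):
                    fh.write(f"{comparison}\t{sp}\t{st}\t{s}\n")
    return manifest
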