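"""End-to-end orchestration: manifest (or simulation) in, report bundle out.

``run_pipeline`` wires the stages together: load (or simulate) peak lists and
peptide tables, group peaks per processing state, mine frequent /
species-exclusive / state-differential / dual / shared markers, mine
characteristic peptide sequences (two-way per state, four-way when exactly
two species carry peptide data), cross-match MALDI panels against
characteristic-peptide masses, and write everything as TSV alongside the
resolved configuration and a stage log.  Reruns with the same configuration
and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import maldi_markers as mm
from . import peptide_markers as pm
from .crossmatch import count_matched_markers, match_markers
from .io_meta import (
    PeakList,
    SampleKey,
    read_manifest,
    read_peaklist,
    read_peptide_table,
    write_marker_report,
)
from .masscalc import PROTON
from .peak_grouping import group_peaks, occurrence_matrix

logger = logging.getLogger("fishmarkers")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of one pipeline run; serialized next to every output."""

    outdir: str
    manifest: Optional[str] = None  # None -> simulate
    seed: int = 0
    gap_tol: float = 0.1  # Da, peak-grouping single-linkage gap
    min_fraction: float = mm.DEFAULT_MIN_FRACTION  # frequency threshold (23/27)
    match_tol: float = 0.1  # Da, cross-list marker comparison
    crossmatch_tol: float = 0.3  # Da, MALDI vs peptide-mass matching
    proton: float = PROTON
    collapse_mods: bool = True
    exclusivity_mode: str = "list_exclusive"
    simulate: Optional[dict] = None  # overrides for SyntheticConfig fields


@dataclass
class PipelineResult:
    outdir: Path
    species_panels: dict  # state -> {species: MarkerPanel}
    state_panels: dict  # species -> (raw_panel, cooked_panel)
    dual_panels: dict  # (species, state) -> MarkerPanel
    shared_pairs: dict  # species -> [(mz_raw, mz_cooked)]
    characteristic: dict  # ("species"|"four_way", species, state) -> CharacteristicSequenceSet
    crossmatch_counts: dict  # (species, state) -> matched marker count


def _load_inputs(config: PipelineConfig, outdir: Path):
    if config.manifest is None:
        from .synthetic import SyntheticConfig, write_simulation

        overrides = dict(config.simulate or {})
        overrides.setdefault("seed", config.seed)
        cfg = SyntheticConfig(**overrides)
        datadir = outdir / "data"
        logger.info("simulating study into %s (seed=%d)", datadir, cfg.seed)
        manifest = write_simulation(cfg, datadir)
    else:
        manifest = Path(config.manifest)
    entries = read_manifest(manifest)
    peaklists: list[PeakList] = []
    peptides = []
    for path, key in entries:
        if not path.exists():
            raise FileNotFoundError(f"manifest references missing file: {path}")
        if key.spot is not None:
            peaklists.append(read_peaklist(path, key))
        else:
            peptides.extend(read_peptide_table(path, key))
    logger.info(
        "loaded %d peak lists and %d peptide observations", len(peaklists), len(peptides)
    )
    return peaklists, peptides


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage and write the report bundle under ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)

    peaklists, peptides = _load_inputs(config, outdir)

    # ---- MALDI mining, one independent analysis per state -----------------
    by_state: dict[str, list[PeakList]] = {}
    for pl in peaklists:
        by_state.setdefault(pl.key.state, []).append(pl)

    matrices: dict[str, object] = {}
    cohorts: dict[str, dict[str, list[SampleKey]]] = {}
    species_panels: dict[str, dict[str, mm.MarkerPanel]] = {}
    for state, pls in sorted(by_state.items()):
        groups = group_peaks(pls, config.gap_tol)
        matrix = occurrence_matrix(groups, [p.key for p in pls])
        matrices[state] = matrix
        per_species: dict[str, list[SampleKey]] = {}
        for p in pls:
            per_species.setdefault(p.key.species, []).append(p.key)
        cohorts[state] = per_species
        logger.info(
            "state=%s: %d spectra -> %d peak groups", state, len(pls), len(groups)
        )
        freq = {
            sp: mm.frequent_mz(matrix, keys, mm.min_count_for(len(keys), config.min_fraction))
            for sp, keys in per_species.items()
        }
        other_peaks = None
        if config.exclusivity_mode == "strict":
            other_peaks = {sp: [] for sp in per_species}
            for p in pls:
                other_peaks[p.key.species].extend(map(float, p.mz))
        if len(freq) >= 2:
            species_panels[state] = mm.species_exclusive_markers(
                freq,
                match_tol=config.match_tol,
                mode=config.exclusivity_mode,
                state=state,
                other_peaks=other_peaks,
            )
            for sp, panel in sorted(species_panels[state].items()):
                logger.info("  %s/%s: %d exclusive markers", sp, state, len(panel))

    state_panels: dict[str, tuple] = {}
    dual_panels: dict[tuple[str, str], mm.MarkerPanel] = {}
    shared_pairs: dict[str, list] = {}
    if "raw" in matrices and "cooked" in matrices:
        both = sorted(set(cohorts["raw"]) & set(cohorts["cooked"]))
        for sp in both:
            n_raw = len(cohorts["raw"][sp])
            raw_p, cooked_p = mm.state_differential_markers(
                matrices["raw"],
                matrices["cooked"],
                cohorts["raw"][sp],
                cohorts["cooked"][sp],
                sp,
                min_count=mm.min_count_for(n_raw, config.min_fraction),
                match_tol=config.match_tol,
            )
            state_panels[sp] = (raw_p, cooked_p)
            for panel in (raw_p, cooked_p):
                sp_panel = species_panels.get(panel.state, {}).get(sp)
                if sp_panel is not None:
                    dual_panels[(sp, panel.state)] = mm.dual_markers(
                        sp_panel, panel, config.match_tol
                    )
            sp_raw = species_panels.get("raw", {}).get(sp)
            sp_cooked = species_panels.get("cooked", {}).get(sp)
            if sp_raw is not None and sp_cooked is not None:
                shared_pairs[sp] = mm.shared_raw_cooked(sp_raw, sp_cooked, config.match_tol)

    # ---- sequence mining ---------------------------------------------------
    characteristic: dict = {}
    pep_cohorts: dict[tuple[str, str], list[SampleKey]] = {}
    obs_by_cohort: dict[tuple[str, str], list] = {}
    for obs in peptides:
        cohort = obs.key.cohort
        keys = pep_cohorts.setdefault(cohort, [])
        if obs.key.drop_spot() not in keys:
            keys.append(obs.key.drop_spot())
        obs_by_cohort.setdefault(cohort, []).append(obs)
    presence = {
        cohort: pm.build_presence(
            obs_by_cohort[cohort], keys, config.collapse_mods,
            cohort_label=f"{cohort[0]}:{cohort[1]}",
        )
        for cohort, keys in pep_cohorts.items()
    }
    pep_species = sorted({sp for sp, _ in pep_cohorts})
    for state in sorted({st for _, st in pep_cohorts}):
        present = [(sp, state) for sp in pep_species if (sp, state) in presence]
        for target in present:
            others = [presence[c] for c in present if c != target]
            if others:
                characteristic[("species",) + target] = pm.characteristic_sequences(
                    presence[target], others
                )
    if len(pep_species) == 2 and len(presence) == 4:
        four = pm.four_way_characteristic(
            [presence[c] for c in sorted(presence)]
        )
        for cohort in sorted(presence):
            label = f"{cohort[0]}:{cohort[1]}"
            characteristic[("four_way",) + cohort] = four[label]

    # ---- cross-platform matching -------------------------------------------
    crossmatch_counts: dict[tuple[str, str], int] = {}
    for (kind, sp, state), charset in sorted(characteristic.items()):
        if kind != "species":
            continue
        panel = species_panels.get(state, {}).get(sp)
        if panel is None or not len(panel):
            continue
        matches = match_markers(
            panel.mz_values,
            sorted(charset.sequences),
            tol=config.crossmatch_tol,
            proton=config.proton,
        )
        crossmatch_counts[(sp, state)] = count_matched_markers(matches, panel.mz_values)
        logger.info(
            "crossmatch %s/%s: %d of %d markers matched",
            sp, state, crossmatch_counts[(sp, state)], len(panel),
        )

    _write_reports(
        outdir, config, species_panels, state_panels, dual_panels,
        shared_pairs, characteristic, crossmatch_counts,
    )
    return PipelineResult(
        outdir=outdir,
        species_panels=species_panels,
        state_panels=state_panels,
        dual_panels=dual_panels,
        shared_pairs=shared_pairs,
        characteristic=characteristic,
        crossmatch_counts=crossmatch_counts,
    )


def _write_reports(
    outdir, config, species_panels, state_panels, dual_panels,
    shared_pairs, characteristic, crossmatch_counts,
) -> None:
    panels = [p for d in species_panels.values() for _, p in sorted(d.items())]
    write_marker_report(panels, outdir / "species_markers.tsv")
    flat = [p for pair in state_panels.values() for p in pair]
    write_marker_report(flat, outdir / "state_markers.tsv")
    write_marker_report(
        [p for _, p in sorted(dual_panels.items())], outdir / "dual_markers.tsv"
    )
    with open(outdir / "shared_raw_cooked.tsv", "w") as fh:
        fh.write("species\tmz_raw\tmz_cooked\n")
        for sp, pairs in sorted(shared_pairs.items()):
            for r, c in pairs:
                fh.write(f"{sp}\t{r:.4f}\t{c:.4f}\n")
    with open(outdir / "characteristic_sequences.tsv", "w") as fh:
        fh.write("comparison\tspecies\tstate\tsequence\n")
        for (kind, sp, state), charset in sorted(characteristic.items()):
            for s in sorted(charset.sequences):
                fh.write(f"{kind}\t{sp}\t{state}\t{s}\n")
    with open(outdir / "protein_ranking.tsv", "w") as fh:
        fh.write("comparison\tspecies\tstate\taccession\tprotein\tn_characteristic\n")
        for (kind, sp, state), charset in sorted(characteristic.items()):
            for acc, name, cnt in charset.top_proteins(5):
                fh.write(f"{kind}\t{sp}\t{state}\t{acc}\t{name}\t{cnt}\n")
    with open(outdir / "crossmatch_counts.tsv", "w") as fh:
        fh.write("species\tstate\tn_markers_matched\n")
        for (sp, state), n in sorted(crossmatch_counts.items()):
            fh.write(f"{sp}\t{state}\t{n}\n")
    with open(outdir / "config.json", "w") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=2, sort_keys=True)
        fh.write("\n")
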