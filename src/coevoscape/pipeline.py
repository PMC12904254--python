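"""End-to-end orchestration of the coevolution analysis stages.

Runs, in dependency order: (optional) synthetic data generation or count
loading, pair enrichment + SSN clustering, SPM fitting, epistasis extraction,
trajectory simulation, well geometry and seed identification, writing flat
TSV/JSON outputs plus a manifest with seeds and content hashes so any stage
can be rerun or audited in isolation.  Every stochastic stage receives a seed
derived deterministically from the master seed and the stage name.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import __version__
from .enrichment import (
    build_ssn,
    detect_communities,
    filter_enriched,
    pair_enrichment,
    pairing_matrix,
    records_to_frame,
)
from .epistasis import decompose, rei
from .geometry import find_wells, well_depth
from .library import (
    LibraryScheme,
    SelectionDataset,
    load_counts,
    load_scheme,
    write_counts,
)
from .seeds import find_seeds, fitness_band, seeds_to_frame
from .simulate import SelectionConfig, sample_landscape, simulate_selection
from .spm import SPMFitConfig, fit_spm
from .walks import simulate_trajectories

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return int(
        np.random.SeedSequence([master_seed, zlib.crc32(stage.encode())]).generate_state(1)[0]
        % 2**31
    )


@dataclass
class PipelineConfig:
    """Stage parameters; the published defaults are kept where they exist."""

    counts_path: Optional[str] = None
    scheme_path: Optional[str] = None
    out_dir: str = "coevoscape_run"
    seed: int = 0
    # synthetic generation (used when counts_path is None)
    synthetic_scheme: Optional[LibraryScheme] = None
    synthetic_selection: Optional[SelectionConfig] = None
    # enrichment / SSN
    ssn_threshold: int = 3
    p_max: float = 0.05
    min_count: int = 20
    community_method: str = "greedy"
    # SPM
    spm_config: Optional[SPMFitConfig] = None
    # epistasis
    max_order: int = 2
    # trajectories / geometry / seeds
    n_trajectories: int = 10_000_000
    k_wells: int = 20
    bootstrap_B: int = 1000
    min_exclusivity: float = 0.9
    min_contribution: float = 0.01
    min_distance: int = 3
    contact_cutoff: float = 4.0
    # stage toggles
    run_enrichment: bool = True
    run_spm: bool = True
    run_epistasis: bool = True
    run_trajectories: bool = True
    run_seeds: bool = True


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all enabled stages; returns the manifest dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "seed": config.seed, "stages": {}, "outputs": {}}

    # --- inputs -----------------------------------------------------------
    if config.counts_path is not None:
        counts_path = Path(config.counts_path)
        if not counts_path.exists():
            raise FileNotFoundError(f"counts file not found: {counts_path}")
        if config.scheme_path is None:
            raise ValueError("scheme_path required when loading counts")
        scheme = load_scheme(config.scheme_path)
        dataset = load_counts(counts_path, scheme)
    else:
        scheme = config.synthetic_scheme or LibraryScheme(
            chain_a_positions=(8, 11, 14),
            chain_b_positions=(29, 30, 33),
            degenerate_codon="DTS",
        )
        sseed = stage_seed(config.seed, "synthetic")
        landscape = sample_landscape(scheme, seed=sseed)
        sel = config.synthetic_selection or SelectionConfig(seed=sseed)
        if sel.seed != sseed:
            from dataclasses import replace

            sel = replace(sel, seed=sseed)
        dataset = simulate_selection(landscape, sel)
        write_counts(dataset, out / "counts.tsv")
        landscape.to_frame().to_csv(out / "true_landscape.tsv", sep="\t", index=False)
        manifest["stages"]["synthetic"] = {"seed": sseed}

    # --- enrichment + SSN -------------------------------------------------
    enriched = None
    if config.run_enrichment:
        records = pair_enrichment(dataset)
        enriched = filter_enriched(records, config.p_max, config.min_count)
        records_to_frame(records, enriched).to_csv(
            out / "enrichment.tsv", sep="\t", index=False
        )
        concat = sorted({r.chain_a + r.chain_b for r in enriched})
        ssn = build_ssn(concat, threshold=config.ssn_threshold)
        ssn = detect_communities(
            ssn, method=config.community_method, seed=stage_seed(config.seed, "ssn")
        )
        with open(out / "communities.tsv", "w") as fh:
            fh.write("sequence\tcommunity\n")
            for node, label in sorted(ssn.communities.items()):
                fh.write(f"{node}\t{label}\n")
        # chain-level cluster labels: modal community of pairs carrying the chain
        labels_a, labels_b = {}, {}
        for rec in enriched:
            label = ssn.communities[rec.chain_a + rec.chain_b]
            labels_a.setdefault(rec.chain_a, {}).setdefault(label, 0)
            labels_a[rec.chain_a][label] += rec.k
            labels_b.setdefault(rec.chain_b, {}).setdefault(label, 0)
            labels_b[rec.chain_b][label] += rec.k
        la = {a: max(d, key=d.get) for a, d in labels_a.items()}
        lb = {b: max(d, key=d.get) for b, d in labels_b.items()}
        if enriched:
            pairing_matrix(enriched, la, lb).to_csv(out / "pairing_matrix.tsv", sep="\t")
        manifest["stages"]["enrichment"] = {
            "n_pairs_enriched": len(enriched),
            "n_unique_sequences": len(concat),
            "n_communities": len(set(ssn.communities.values())),
        }

    # --- SPM ---------------------------------------------------------------
    model = None
    if config.run_spm:
        spm_cfg = config.spm_config or SPMFitConfig()
        from dataclasses import replace

        spm_cfg = replace(spm_cfg, seed=stage_seed(config.seed, "spm"))
        model = fit_spm(dataset, spm_cfg)
        model.save(out / "spm_model.npz")
        universe = ["".join(p) for p in dataset.sequences()]
        scores = model.score(universe)
        with open(out / "spm_scores.tsv", "w") as fh:
            fh.write("sequence\tround\tfitness\n")
            for s, f in zip(universe, scores):
                fh.write(f"{s}\tglobal\t{f:.6g}\n")
        manifest["stages"]["spm"] = {
            "seed": spm_cfg.seed,
            "final_nll": model.history["nll"][-1] if model.history.get("nll") else None,
        }

    fitness_fn = (lambda seqs: model.score(seqs)) if model is not None else None

    # --- epistasis ----------------------------------------------------------
    if config.run_epistasis and fitness_fn is not None:
        report = decompose(
            fitness_fn,
            scheme,
            max_order=config.max_order,
            seed=stage_seed(config.seed, "epistasis"),
        )
        report.to_frame().to_csv(out / "epistasis.tsv", sep="\t", index=False)
        report.effects_frame().to_csv(out / "effect_sizes.tsv", sep="\t", index=False)
        manifest["stages"]["epistasis"] = {
            "rei_order2": rei(report, 2),
            "n_terms": len(report.terms),
        }

    # --- trajectories + geometry -------------------------------------------
    ensemble = None
    if config.run_trajectories and fitness_fn is not None:
        wseed = stage_seed(config.seed, "walks")
        ensemble = simulate_trajectories(
            fitness_fn, scheme, config.n_trajectories, seed=wseed, track_visits=True
        )
        ensemble.to_frame().to_csv(out / "trajectories.tsv", sep="\t", index=False)
        geo = find_wells(ensemble, fitness_fn, k=config.k_wells)
        geo = well_depth(geo, fitness_fn, scheme)
        geo.to_frame().to_csv(out / "wells.tsv", sep="\t", index=False)
        manifest["stages"]["trajectories"] = {
            "seed": wseed,
            "n_trajectories": config.n_trajectories,
            "n_terminals": len(ensemble.terminal_counts),
        }

    # --- seeds ---------------------------------------------------------------
    if config.run_seeds and ensemble is not None:
        try:
            band = fitness_band(dataset, fitness_fn)
        except ValueError:
            band = None
        if band is not None:
            candidates = find_seeds(
                ensemble,
                fitness_fn,
                band,
                min_exclusivity=config.min_exclusivity,
                min_contribution=config.min_contribution,
                min_distance=config.min_distance,
            )
            seeds_to_frame(candidates).to_csv(out / "seeds.tsv", sep="\t", index=False)
            manifest["stages"]["seeds"] = {
                "band": list(band),
                "n_candidates": len(candidates),
            }

    for p in sorted(out.iterdir()):
        if p.is_file() and p.name != "manifest.json":
            manifest["outputs"][p.name] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
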