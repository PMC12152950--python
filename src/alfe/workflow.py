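"""End-to-end synthetic pipeline: filter cascade -> pre-AL labelling ->
active learning -> perturbation-map conversion -> budgeted selection ->
reports.

The pipeline mirrors the production hit-optimization campaign but runs on
the synthetic generators: library enumeration stands in for the vendor
catalogue, the group-contribution oracle stands in for TI simulation, and
mock docking tables stand in for the docking engines.  Every stage logs its
in/out counts and the run is deterministic under the root seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import al as al_mod
from . import chemlib, structure_prep, synth, thermo
from .config import PipelineConfig

logger = logging.getLogger(__name__)

STAGES = (
    "library",
    "hygiene",
    "substructure",
    "stage1_filter",
    "stage2_filter",
    "pre_al",
    "al_acquired",
    "candidates",
)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute the full synthetic campaign and write reports into ``out_dir``.

    Outputs: ``counts.csv`` (per-stage molecule counts), ``candidates.csv``
    (final budgeted selection), ``affinities.csv`` (absolute free energies
    from the perturbation map), ``history.json`` (AL iterations),
    ``tsne.csv``/``tsne.png`` (chemical-space projection), ``run.log``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    logging.getLogger("alfe").addHandler(handler)
    counts: dict[str, int] = {}
    try:
        return _run(config, out, counts)
    finally:
        _write_counts(counts, out / "counts.csv")
        logging.getLogger("alfe").removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, out: Path, counts: dict[str, int]) -> Path:
    rng_seed = config.seed

    # 1. library enumeration + hygiene
    library = synth.default_library(n_max=config.library_size, seed=rng_seed)
    counts["library"] = len(library)
    logger.info("library: %d molecules", len(library))

    report = chemlib.RejectionReport()
    library = chemlib.canonicalize_and_dedup(library, report)
    counts["hygiene"] = len(library)

    library = chemlib.substructure_filter(library, config.closest_smarts)
    counts["substructure"] = len(library)
    logger.info("substructure filter: %d molecules", len(library))

    # 2. mock docking + two-stage filter cascade
    oracle_spec = synth.default_oracle_spec(seed=rng_seed, noise_sd=config.oracle_noise_sd)
    poses = synth.mock_docking(
        library, oracle_spec, seed=rng_seed, pass_fraction=config.docking_pass_fraction
    )
    best1 = structure_prep.best_pose_per_molecule(poses, structure_prep.RmsdField.INDOLE)
    stage1_ids = set(
        structure_prep.stage1_filter(
            best1, config.filters.rmsd_indole_max, config.filters.score_max
        )
    )
    counts["stage1_filter"] = len(stage1_ids)
    poses1 = [p for p in poses if p.molecule_id in stage1_ids]
    best2 = structure_prep.best_pose_per_molecule(poses1, structure_prep.RmsdField.MURCKO)
    stage2_ids = set(
        structure_prep.stage2_filter(
            best2, config.filters.rmsd_murcko_max, config.filters.score_max,
            config.filters.clash_max,
        )
    )
    counts["stage2_filter"] = len(stage2_ids)
    pool = [rec for rec in library if rec.id in stage2_ids]
    logger.info("filter cascade: %d -> %d -> %d", len(library), len(stage1_ids), len(stage2_ids))

    # 3. features; split the pool into two "hit series" by scaffold-half
    by_id = {rec.id: rec for rec in pool}
    features = {rec.id: chemlib.featurize(rec).bits for rec in pool}
    groups = {
        rec.id: ("hit1" if i % 4 != 3 else "hit2") for i, rec in enumerate(pool)
    }
    feats_by_rep = {chemlib.FingerprintKind.ECFP6_2048.value: features}

    # 4. pre-AL training set labelled by the oracle (stand-in for TI runs)
    rng = np.random.default_rng(rng_seed)
    hit1_pool = [r.id for r in pool if groups[r.id] == "hit1"]
    pre_al_ids = [
        hit1_pool[int(i)]
        for i in rng.choice(len(hit1_pool), size=min(config.pre_al_size, len(hit1_pool)), replace=False)
    ]
    train = al_mod.TrainingSet()
    for mol_id in pre_al_ids:
        train.add(mol_id, synth.affinity_oracle(by_id[mol_id], oracle_spec), "pre_AL")
    counts["pre_al"] = len(train)

    # 5. active learning
    state = al_mod.run_al_loop(
        pool_ids=[r.id for r in pool],
        pool_groups=groups,
        features_by_representation=feats_by_rep,
        oracle=lambda mol_id: synth.affinity_oracle(by_id[mol_id], oracle_spec),
        init_train=train,
        config=config.al,
    )
    counts["al_acquired"] = len(state.acquired_ids)
    state.to_json(out / "history.json")

    # 6. perturbation-map conversion anchored at the best pre-AL molecule
    anchor_id = min(pre_al_ids, key=lambda m: state.training.labels[state.training.ids.index(m)])
    pmap = thermo.PerturbationMap()
    anchor_label = state.training.labels[state.training.ids.index(anchor_id)]
    for mol_id, label in zip(state.training.ids, state.training.labels):
        if mol_id == anchor_id:
            continue
        pmap.add_edge(anchor_id, mol_id, ddg=label - anchor_label, stderr=0.1)
    affinities = pmap.to_abfe([(anchor_id, config.anchor_dg)])
    thermo.write_affinities(affinities, out / "affinities.csv")

    # 7. budgeted final selection over the labelled set
    shift = config.anchor_dg - anchor_label
    scores = {
        mol_id: label + shift
        for mol_id, label in zip(state.training.ids, state.training.labels)
    }
    budget = config.budget
    candidates = al_mod.select_candidates(
        scores,
        features,
        budget_total=min(budget.total, len(scores)),
        greedy_n=min(budget.greedy, len(scores) - budget.diverse),
        diverse_n=budget.diverse,
        diverse_filter=lambda m: groups.get(m) == "hit2",
    )
    counts["candidates"] = len(candidates)
    pd.DataFrame(
        {"id": candidates, "dg_abs_kcal": [round(scores[c], 2) for c in candidates]}
    ).to_csv(out / "candidates.csv", index=False)

    # 8. chemical-space projection of the screened pool
    if len(pool) > config.tsne_perplexity * 3:
        coords = al_mod.project_chemical_space(
            np.vstack([features[r.id] for r in pool]),
            seed=rng_seed,
            perplexity=config.tsne_perplexity,
        )
        tsne_df = pd.DataFrame(
            {
                "id": [r.id for r in pool],
                "x": coords[:, 0],
                "y": coords[:, 1],
                "labelled": [r.id in set(state.training.ids) for r in pool],
            }
        )
        tsne_df.to_csv(out / "tsne.csv", index=False)
        _plot_tsne(tsne_df, out / "tsne.png")
    return out


def _plot_tsne(df: pd.DataFrame, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    unl = df[~df["labelled"]]
    lab = df[df["labelled"]]
    ax.scatter(unl["x"], unl["y"], s=8, c="lightgray", label="pool")
    ax.scatter(lab["x"], lab["y"], s=12, c="crimson", label="labelled")
    ax.set_xlabel("t-SNE 1")
    ax.set_ylabel("t-SNE 2")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _write_counts(counts: dict[str, int], path: Path) -> None:
    rows = [{"stage": s, "count": counts.get(s, 0)} for s in STAGES if s in counts]
    pd.DataFrame(rows).to_csv(path, index=False)


def report_counts(run_dir: str | Path) -> pd.DataFrame:
    """Per-stage molecule counts of a completed run (absent stages count -1)."""
    path = Path(run_dir) / "counts.csv"
    if not path.exists():
        raise FileNotFoundError(f"no counts.csv in {run_dir}")
    df = pd.read_csv(path)
    present = set(df["stage"])
    missing = [{"stage": s, "count": -1} for s in STAGES if s not in present]
    if missing:
        df = pd.concat([df, pd.DataFrame(missing)], ignore_index=True)
    return df
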