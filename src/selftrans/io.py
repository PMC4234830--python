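"""Readers and writers for the package's TSV schemas, run configuration
and the pipeline that chains the analysis stages.

All tables are UTF-8 tab-separated files with ``NA`` for missing
values.  Readers validate hard: unknown columns, type violations and
constraint violations (e.g. more wild-type alleles than sampled
alleles) fail with the offending row number rather than being coerced.
Every synthetic table travels with a ``<name>.truth.json`` sidecar
holding its generating truth, and every pipeline run writes its
resolved configuration next to its outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import SimulationParams
from .diversity import (
    SNPGenotypeMatrix,
    composite_ld_mean_r2,
    homozygosity,
    maf_filter,
    DiversitySummary,
)
from .fitness import (
    CompetitionRecord,
    MaleFitnessRecord,
    block_center_and_delta,
    competition_fitness,
)
from .infer import TrajectoryObservation, default_alpha_grid, grid_likelihood_search
from .synth import (
    SyntheticTruth,
    gen_competition_dataset,
    gen_snp_dataset,
    gen_trajectory_dataset,
)

__all__ = [
    "SchemaError",
    "RunConfig",
    "read_trajectory_table",
    "write_trajectory_table",
    "read_competition_table",
    "write_competition_table",
    "read_male_fitness_table",
    "write_male_fitness_table",
    "read_snp_matrix",
    "write_snp_matrix",
    "write_truth_sidecar",
    "read_truth_sidecar",
    "run_pipeline",
]


class SchemaError(ValueError):
    """A table violated its schema; the message names the row."""


def _read_tsv(path: str | Path, required: list[str], optional: list[str] = ()) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    unknown = [c for c in df.columns if c not in list(required) + list(optional)]
    if unknown:
        raise SchemaError(f"{path}: unknown columns {unknown}")
    return df


def _int_cell(df_value, path, row, col) -> int:
    try:
        as_float = float(df_value)
        as_int = int(as_float)
        if as_int != as_float:
            raise ValueError
        return as_int
    except (TypeError, ValueError):
        raise SchemaError(f"{path}: row {row}: column {col!r} must be an integer, got {df_value!r}")


def _float_cell(df_value, path, row, col) -> float:
    try:
        return float(df_value)
    except (TypeError, ValueError):
        raise SchemaError(f"{path}: row {row}: column {col!r} must be numeric, got {df_value!r}")


# --- trajectory (fog-2 genotyping) tables ---------------------------------

def write_trajectory_table(observations: list[TrajectoryObservation], path: str | Path) -> None:
    rows = []
    for obs in observations:
        rows.append(
            {
                "population_id": obs.population_id,
                "generation": obs.generation,
                "n_individuals": obs.n_individuals,
                "n_wt_alleles": obs.n_wt_alleles,
                "male_freq": "NA" if obs.male_freq is None else obs.male_freq,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_trajectory_table(path: str | Path) -> list[TrajectoryObservation]:
    df = _read_tsv(
        path,
        required=["population_id", "generation", "n_individuals", "n_wt_alleles"],
        optional=["male_freq"],
    )
    out = []
    for row, rec in df.iterrows():
        n_ind = _int_cell(rec["n_individuals"], path, row, "n_individuals")
        k = _int_cell(rec["n_wt_alleles"], path, row, "n_wt_alleles")
        if not 0 <= k <= 2 * n_ind:
            raise SchemaError(
                f"{path}: row {row}: n_wt_alleles={k} outside [0, {2 * n_ind}] "
                f"(2 x n_individuals)"
            )
        mf = rec.get("male_freq")
        male_freq = None if (mf is None or pd.isna(mf)) else _float_cell(mf, path, row, "male_freq")
        try:
            out.append(
                TrajectoryObservation(
                    population_id=str(rec["population_id"]),
                    generation=_int_cell(rec["generation"], path, row, "generation"),
                    n_individuals=n_ind,
                    n_wt_alleles=k,
                    male_freq=male_freq,
                )
            )
        except ValueError as exc:
            raise SchemaError(f"{path}: row {row}: {exc}") from exc
    return out


# --- competition tables ----------------------------------------------------

_COMP_COLS = [
    "block", "population_id", "setup_wt", "setup_gfp",
    "final_gfp_pos", "final_gfp_neg", "male_freq_wt", "male_freq_gfp",
]


def write_competition_table(records: list[CompetitionRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "block": r.block,
                "population_id": r.population_id,
                "setup_wt": r.setup_wt_count,
                "setup_gfp": r.setup_gfp_count,
                "final_gfp_pos": r.final_gfp_pos,
                "final_gfp_neg": r.final_gfp_neg,
                "male_freq_wt": r.male_freq_wt,
                "male_freq_gfp": r.male_freq_gfp,
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)


def read_competition_table(path: str | Path) -> list[CompetitionRecord]:
    df = _read_tsv(path, required=_COMP_COLS)
    out = []
    for row, rec in df.iterrows():
        try:
            out.append(
                CompetitionRecord(
                    block=str(rec["block"]),
                    population_id=str(rec["population_id"]),
                    setup_wt_count=_float_cell(rec["setup_wt"], path, row, "setup_wt"),
                    setup_gfp_count=_float_cell(rec["setup_gfp"], path, row, "setup_gfp"),
                    final_gfp_pos=_float_cell(rec["final_gfp_pos"], path, row, "final_gfp_pos"),
                    final_gfp_neg=_float_cell(rec["final_gfp_neg"], path, row, "final_gfp_neg"),
                    male_freq_wt=_float_cell(rec["male_freq_wt"], path, row, "male_freq_wt"),
                    male_freq_gfp=_float_cell(rec["male_freq_gfp"], path, row, "male_freq_gfp"),
                )
            )
        except ValueError as exc:
            raise SchemaError(f"{path}: row {row}: {exc}") from exc
    return out


# --- male fitness tables ---------------------------------------------------

def write_male_fitness_table(records: list[MaleFitnessRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "plate": r.plate,
                "females_transferred": r.females_transferred,
                "progeny_gfp_pos": r.progeny_gfp_pos,
                "progeny_gfp_neg": r.progeny_gfp_neg,
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)


def read_male_fitness_table(path: str | Path) -> list[MaleFitnessRecord]:
    df = _read_tsv(
        path, required=["plate", "females_transferred", "progeny_gfp_pos", "progeny_gfp_neg"]
    )
    out = []
    for row, rec in df.iterrows():
        try:
            out.append(
                MaleFitnessRecord(
                    plate=str(rec["plate"]),
                    females_transferred=_int_cell(rec["females_transferred"], path, row, "females_transferred"),
                    progeny_gfp_pos=_int_cell(rec["progeny_gfp_pos"], path, row, "progeny_gfp_pos"),
                    progeny_gfp_neg=_int_cell(rec["progeny_gfp_neg"], path, row, "progeny_gfp_neg"),
                )
            )
        except ValueError as exc:
            raise SchemaError(f"{path}: row {row}: {exc}") from exc
    return out


# --- SNP genotype matrices --------------------------------------------------

def write_snp_matrix(matrix: SNPGenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(matrix.genotypes, columns=matrix.loci)
    df.insert(0, "population", matrix.populations)
    df.insert(0, "individual_id", matrix.individual_ids)
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.0f")


def read_snp_matrix(path: str | Path) -> SNPGenotypeMatrix:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    for col in ("individual_id", "population"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    loci = [c for c in df.columns if c not in ("individual_id", "population")]
    genos = df[loci].to_numpy(dtype=float)
    bad = ~(np.isnan(genos) | np.isin(genos, (0.0, 1.0, 2.0)))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise SchemaError(
            f"{path}: row {r}: locus {loci[c]!r} has genotype code "
            f"{genos[r, c]!r}, expected 0/1/2/NA"
        )
    return SNPGenotypeMatrix(
        genotypes=genos,
        populations=df["population"].to_numpy(),
        loci=loci,
        individual_ids=df["individual_id"].astype(str).tolist(),
    )


# --- truth sidecars ---------------------------------------------------------

def write_truth_sidecar(truth: SyntheticTruth, table_path: str | Path) -> Path:
    path = Path(str(table_path) + ".truth.json")
    path.write_text(json.dumps(truth.as_dict(), indent=2) + "\n")
    return path


def read_truth_sidecar(table_path: str | Path) -> dict:
    return json.loads(Path(str(table_path) + ".truth.json").read_text())


# --- run configuration and the pipeline -------------------------------------

@dataclass
class RunConfig:
    """Resolved configuration of a pipeline run.

    Seeds every stage, mirrors the simulation parameter names and is
    written verbatim next to the outputs of each run.
    """

    seed: int = 0
    # synthetic trajectory + alpha inference
    true_alpha: float = 1.41
    n_populations: int = 3
    census_size: int = 2000
    sample_generations: tuple[int, ...] = (5, 15, 25, 35)
    n_genotyped: int = 48
    grid_min: float = 0.0
    grid_max: float = 2.0
    grid_points: int = 51
    likelihood_reps: int = 20
    ci_drop: float = 3.84
    # synthetic competition + fitness
    true_w: float = 0.5
    n_blocks: int = 12
    reference_label: str = "ANC"
    # synthetic SNPs + diversity
    selfing_rate: float = 0.5
    n_snp_individuals: int = 48
    n_loci: int = 58
    maf_threshold: float = 0.05

    def __post_init__(self) -> None:
        if self.grid_points < 2:
            raise ValueError("grid_points must be >= 2")
        if self.grid_min >= self.grid_max:
            raise ValueError("grid_min must be < grid_max")
        if self.likelihood_reps < 1:
            raise ValueError("likelihood_reps must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"{path}: unknown config keys {sorted(unknown)}")
        if "sample_generations" in raw:
            raw["sample_generations"] = tuple(raw["sample_generations"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["sample_generations"] = list(data["sample_generations"])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Run synthesize -> infer alpha -> fitness -> diversity, writing every
    stage's table and a summary JSON into ``out_dir``.

    Returns the summary dict (also written to ``summary.json``).  All
    randomness derives from ``config.seed``; rerunning with the same
    config reproduces every output byte for byte.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    log: list[str] = []
    summary: dict = {"seed": config.seed}
    seeds = np.random.SeedSequence(config.seed).generate_state(4)

    # Stage 1: synthetic trajectories + alpha inference.
    observations, truth = gen_trajectory_dataset(
        true_alpha=config.true_alpha,
        n_populations=config.n_populations,
        sample_generations=config.sample_generations,
        n_genotyped=config.n_genotyped,
        census_size=config.census_size,
        seed=int(seeds[0] % 2**31),
    )
    traj_path = out / "trajectories.tsv"
    write_trajectory_table(observations, traj_path)
    write_truth_sidecar(truth, traj_path)
    params = SimulationParams(
        alpha=config.true_alpha, census_size=config.census_size, seed=int(seeds[1] % 2**31)
    )
    result = grid_likelihood_search(
        observations,
        params,
        grid=default_alpha_grid(config.grid_min, config.grid_max, config.grid_points),
        n_reps=config.likelihood_reps,
        seed=int(seeds[1] % 2**31),
        ci_drop=config.ci_drop,
    )
    pd.DataFrame(
        {"alpha": result.alpha_grid, "compound_loglik": result.compound_loglik}
    ).to_csv(out / "alpha_likelihood.tsv", sep="\t", index=False)
    summary["alpha"] = {
        "ml": result.ml_alpha,
        "ci_lower": result.ci_lower,
        "ci_upper": result.ci_upper,
        "boundary_ml": result.boundary_ml,
    }
    log.append(f"infer-alpha: ML={result.ml_alpha} CI=[{result.ci_lower}, {result.ci_upper}]")

    # Stage 2: synthetic competition + fitness estimation.
    records, w_truth = gen_competition_dataset(
        true_w=config.true_w,
        n_blocks=config.n_blocks,
        reference_label=config.reference_label,
        seed=int(seeds[2] % 2**31),
    )
    comp_path = out / "competition.tsv"
    write_competition_table(records, comp_path)
    write_truth_sidecar(w_truth, comp_path)
    estimates = block_center_and_delta(
        [competition_fitness(r) for r in records], config.reference_label
    )
    fit_df = pd.DataFrame(
        [
            {"block": e.block, "population_id": e.population_id, "w": e.w, "w_t": e.w_t}
            for e in estimates
        ]
    )
    fit_df.to_csv(out / "fitness_estimates.tsv", sep="\t", index=False)
    focal = fit_df[fit_df.population_id != config.reference_label]["w_t"]
    summary["fitness"] = {"mean_w_t": float(focal.mean()), "n_records": int(len(fit_df))}
    log.append(f"fitness: mean w_t={focal.mean():.4f} over {len(focal)} records")

    # Stage 3: synthetic SNPs + diversity.
    matrix, snp_truth = gen_snp_dataset(
        n_individuals=config.n_snp_individuals,
        n_loci=config.n_loci,
        selfing_rate=config.selfing_rate,
        seed=int(seeds[3] % 2**31),
    )
    snp_path = out / "snps.tsv"
    write_snp_matrix(matrix, snp_path)
    write_truth_sidecar(snp_truth, snp_path)
    filtered, dropped = maf_filter(matrix, config.maf_threshold)
    div = DiversitySummary(
        population=str(matrix.populations[0]),
        one_minus_ho=homozygosity(filtered),
        mean_r2=composite_ld_mean_r2(matrix, config.maf_threshold),
        n_loci_used=filtered.shape[1],
    )
    summary["diversity"] = {
        "one_minus_ho": div.one_minus_ho,
        "mean_r2": div.mean_r2,
        "n_loci_used": div.n_loci_used,
        "n_loci_dropped_maf": len(dropped),
    }
    log.append(
        f"diversity: 1-Ho={div.one_minus_ho:.4f} mean r2={div.mean_r2} "
        f"({div.n_loci_used} loci)"
    )

    (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    (out / "run.log").write_text("\n".join(log) + "\n")
    return summary
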