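"""Pipeline orchestration: run all stages in dependency order, write every
stage's outputs, and record a manifest with seeds, checksums and row counts.

The stage order is simulate/ingest -> osa-params -> diversity -> associate
-> [impute] -> heterogeneity -> gmm -> cooccur -> outcomes.  Every source of
randomness derives from the config seed, so identical configs give
byte-identical output trees.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, cooccurrence, diversity, downstream, gmm, heterogeneity, imputation, io, osa, synth

log = logging.getLogger("osagut")


@dataclass
class PipelineConfig:
    """Top-level configuration (YAML-loadable key-value schema).

    ``cohort`` holds :class:`~osagut.synth.CohortConfig` fields for the
    simulate stage; ``input_dir`` switches to ingesting an existing cohort
    directory instead.  Stage toggles, the FDR level and the permutation /
    bootstrap counts are recorded in the output manifest.
    """

    out_dir: str = "osagut_output"
    seed: int = 0
    input_dir: str | None = None
    cohort: dict = field(default_factory=dict)
    fdr: float = 0.05
    n_permutations: int = 999
    bootstrap_iterations: int = 1000
    permanova_max_n: int | None = None
    run_imputation: bool = True
    run_heterogeneity: bool = True
    run_gmm: bool = True
    run_cooccurrence: bool = True
    run_outcomes: bool = True
    run_diversity: bool = True
    heterogeneity_max_species: int | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _load_cohort_dir(input_dir: Path) -> synth.Cohort:
    """Ingest a cohort directory written by the simulate stage."""
    exposures = io.read_exposures(input_dir / io.FILENAMES["exposures"])
    covariates = io.read_covariates(input_dir / io.FILENAMES["covariates"])
    abundance = io.read_abundance(input_dir / io.FILENAMES["abundance"])
    ko = io.read_ko(input_dir / io.FILENAMES["ko"], known_species=list(abundance.columns))
    gmms = gmm.read_gmm_file(input_dir / io.FILENAMES["gmm_definitions"])
    recordings = pd.read_csv(input_dir / io.FILENAMES["recordings"], sep="\t").set_index("participant_id")
    events = pd.read_csv(input_dir / io.FILENAMES["events"], sep="\t")
    outcomes = pd.read_csv(input_dir / io.FILENAMES["outcomes"], sep="\t").set_index("participant_id")
    for col in ("antihypertensive_med", "antidiabetic_med"):
        outcomes[col] = outcomes[col].astype(bool)
    truth = synth.SyntheticTruth.from_dict(io.read_json(input_dir / io.FILENAMES["truth"]))
    n = len(exposures)
    config = synth.CohortConfig(n_participants=n, n_species=abundance.shape[1])
    return synth.Cohort(config, truth, exposures, covariates, abundance, ko, gmms, recordings, events, outcomes)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured stages; returns the output directory."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "fdr": config.fdr,
        "n_permutations": config.n_permutations,
        "bootstrap_iterations": config.bootstrap_iterations,
        "stages": {},
        "inputs": {},
    }

    # -- simulate / ingest --------------------------------------------------
    if config.input_dir is None:
        cohort_cfg = synth.CohortConfig(**{"seed": config.seed, **config.cohort})
        cohort = synth.generate_cohort(cohort_cfg)
        cohort_dir = out / "cohort"
        manifest["inputs"] = io.write_cohort(cohort, cohort_dir)
        manifest["cohort_config"] = dataclasses.asdict(cohort_cfg)
        log.info("simulate: n=%d participants, %d species", cohort_cfg.n_participants, cohort_cfg.n_species)
    else:
        cohort = _load_cohort_dir(Path(config.input_dir))
        manifest["inputs"] = {
            name: io.sha256_file(Path(config.input_dir) / fname)
            for name, fname in io.FILENAMES.items()
            if (Path(config.input_dir) / fname).exists()
        }
        log.info("ingest: %s", config.input_dir)
    manifest["stages"]["cohort"] = {"n_participants": len(cohort.exposures)}

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1000]))

    # -- osa-params ---------------------------------------------------------
    params = osa.compute_parameters_table(cohort.recordings, cohort.events)
    groups = osa.assign_severity_groups(params)
    io.write_results(params.reset_index(names="participant_id"), out / "osa_parameters.tsv")
    io.write_results(groups.reset_index(names="participant_id"), out / "severity_groups.tsv")
    n_invalid = int((~params["ahi_valid"]).sum())
    log.info("osa-params: %d analyzed, %d AHI-invalid (flow < 4 h)", len(params), n_invalid)
    manifest["stages"]["osa_params"] = {"n": len(params), "n_ahi_invalid": n_invalid}

    exposures = params[["ahi", "t90", "odi"]]
    covariates = cohort.covariates.copy()
    covariates["energy"] = osa.clean_energy_intake(covariates["energy"])

    # -- diversity ----------------------------------------------------------
    if config.run_diversity:
        shannon = diversity.shannon_table(cohort.abundance)
        io.write_results(shannon.rename_axis("participant_id").reset_index(), out / "shannon.tsv")
        div_assoc = association.diversity_associations(shannon, exposures, covariates)
        io.write_results(div_assoc, out / "diversity_associations.tsv")

        sub = np.arange(len(cohort.abundance))
        if config.permanova_max_n is not None and len(sub) > config.permanova_max_n:
            sub = np.sort(rng.choice(sub, size=config.permanova_max_n, replace=False))
        ab_sub = cohort.abundance.iloc[sub]
        dm = diversity.bray_curtis(ab_sub)
        ordination = diversity.pcoa(dm, n_axes=2)
        coords = pd.DataFrame(ordination.coordinates, index=ab_sub.index, columns=["axis1", "axis2"])
        io.write_results(coords.reset_index(names="participant_id"), out / "pcoa_coordinates.tsv")
        io.write_json(
            {
                "eigenvalues": ordination.eigenvalues[:20].tolist(),
                "explained_variance": ordination.explained_variance.tolist(),
            },
            out / "pcoa_eigen.json",
        )
        perm_rows = []
        cov_main = covariates[list(association.MAIN_COVARIATES)]
        for col in ("ahi_group", "t90_group", "odi_group"):
            g = groups[col].iloc[sub]
            res = diversity.permanova(
                dm, g, cov_main.iloc[sub], n_permutations=config.n_permutations,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            perm_rows.append((col, res.r2, res.pseudo_f, res.p, res.n))
        io.write_results(
            pd.DataFrame(perm_rows, columns=["grouping", "r2", "pseudo_f", "p", "n"]),
            out / "permanova.tsv",
        )
        manifest["stages"]["diversity"] = {"n_permanova": len(ab_sub)}
    else:
        shannon = diversity.shannon_table(cohort.abundance)

    # -- associate ----------------------------------------------------------
    cascade = association.run_cascade(exposures, cohort.abundance, covariates, fdr=config.fdr)
    io.write_results(cascade.table, out / "associations.tsv")
    hits = cascade.hits_union(("t90", "odi"))
    log.info(
        "associate: %d species retained; stage-3 hits ahi=%d t90=%d odi=%d",
        len(cascade.retained_species),
        len(cascade.hits.get("ahi", [])),
        len(cascade.hits.get("t90", [])),
        len(cascade.hits.get("odi", [])),
    )
    manifest["stages"]["associate"] = {
        "n_retained_species": len(cascade.retained_species),
        "hits": {k: len(v) for k, v in cascade.hits.items()},
    }
    sens = association.sensitivity_suite(cascade.hits, exposures, cohort.abundance, covariates, fdr=config.fdr)
    sens_table = pd.concat(
        [t.assign(variant=name) for name, t in sens.items() if len(t)], ignore_index=True
    ) if any(len(t) for t in sens.values()) else pd.DataFrame()
    io.write_results(sens_table, out / "sensitivity.tsv")

    # -- impute -------------------------------------------------------------
    if config.run_imputation and hits:
        imp = imputation.imputed_cascade(
            exposures, cohort.abundance, covariates, hits, shannon=shannon,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        io.write_results(imp, out / "imputed_associations.tsv")
        manifest["stages"]["impute"] = {"n_species": len(imp)}

    # -- heterogeneity ------------------------------------------------------
    if config.run_heterogeneity and hits:
        strata = heterogeneity.split_by_hemoglobin(covariates)
        het_species = hits
        if config.heterogeneity_max_species is not None:
            het_species = hits[: config.heterogeneity_max_species]
        het = heterogeneity.heterogeneity_screen(
            het_species, exposures, cohort.abundance, covariates, strata,
            b=config.bootstrap_iterations, seed=int(rng.integers(0, 2**31 - 1)),
        )
        io.write_results(het, out / "heterogeneity.tsv")
        manifest["stages"]["heterogeneity"] = {"n_rows": len(het)}

    # -- gmm ----------------------------------------------------------------
    if config.run_gmm:
        presence = gmm.annotate_species(cohort.ko_profiles, cohort.gmm_definitions)
        io.write_results(presence.reset_index(), out / "gmm_presence.tsv")
        enr_tables = []
        ext_model = association.default_models()["extended"]
        feats = cohort.abundance[cascade.retained_species]
        for exp_name in ("t90", "odi"):
            res = association.run_model(exposures[exp_name], feats, covariates, ext_model)
            if not len(res):
                continue
            for direction in ("positive", "negative"):
                e = gmm.gmm_enrichment(res, presence, direction)
                e.insert(0, "exposure", exp_name)
                enr_tables.append(e)
        enr = pd.concat(enr_tables, ignore_index=True) if enr_tables else pd.DataFrame()
        io.write_results(enr, out / "gmm_enrichment.tsv")
        manifest["stages"]["gmm"] = {"n_modules_tested": len(enr)}

    # -- cooccur ------------------------------------------------------------
    if config.run_cooccurrence and len(hits) >= 2:
        pres = cooccurrence.presence_matrix(cohort.abundance, hits)
        net = cooccurrence.build_network(pres, alpha=0.05)
        io.write_results(net, out / "cooccurrence.tsv")
        manifest["stages"]["cooccur"] = {"n_pairs": len(net)}

    # -- outcomes -----------------------------------------------------------
    if config.run_outcomes and hits:
        oa = downstream.outcome_associations(
            hits, cohort.abundance, cohort.outcomes, covariates, exposures, fdr=config.fdr
        )
        io.write_results(oa, out / "outcome_associations.tsv")
        manifest["stages"]["outcomes"] = {"n_rows": len(oa)}

    manifest["runtime_s"] = round(time.time() - t0, 2)
    io.write_json(manifest, out / "manifest.json")
    log.info("pipeline complete in %.1f s -> %s", manifest["runtime_s"], out)
    return out
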