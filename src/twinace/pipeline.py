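"""End-to-end analysis pipeline and report writers.

``run_pipeline`` drives the whole twin analysis from a config mapping (or
YAML file): load or simulate data, residualize on covariates, write the
phenotypic report (descriptives, correlation block, ICCs, CFA), the
univariate model ladder per trait, the multivariate ladder, the
genetic/environmental correlation matrix and the common-pathway variance
decomposition.  Stage errors are reported with the stage name; outputs of
completed stages are preserved.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cfa import OneFactorCFA
from .dataset import TwinDataset, load_dataset
from .exceptions import TwinaceError
from .multivariate import MultivariateBiometricModel
from .phenotypic import table1_report
from .preprocess import residualize_covariates
from .selection import compare_multivariate, compare_univariate, select_model
from .simulate import STUDY_N_DZ, STUDY_N_MZ, simulate as simulate_pairs, study_mirror_spec

log = logging.getLogger("twinace")


class StageError(TwinaceError):
    def __init__(self, stage, cause):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


DEFAULT_CONFIG = {
    "seed": 0,
    "covariates": ["age", "sex"],
    "univariate_models": ["ACE", "AE", "CE", "E"],
    "multivariate_structures": [
        "cholesky",
        "independent_pathway",
        "common_pathway",
    ],
    "components": ["A", "E"],
    "n_restarts": 3,
    "criterion": "BIC",
}


def _load_config(config):
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config or {})
    return cfg


def _obtain_data(cfg) -> TwinDataset:
    if "input" in cfg:
        inp = cfg["input"]
        return load_dataset(inp["csv"], inp["schema"])
    simcfg = cfg.get("simulate", {"spec": "study_mirror"})
    if simcfg.get("spec", "study_mirror") != "study_mirror":
        raise ValueError("only the 'study_mirror' simulation spec is built in")
    spec = study_mirror_spec()
    return simulate_pairs(
        spec,
        n_mz=simcfg.get("n_mz", STUDY_N_MZ),
        n_dz=simcfg.get("n_dz", STUDY_N_DZ),
        seed=cfg["seed"],
    )


def run_pipeline(config, output_dir=None) -> dict:
    """Execute the full analysis; returns a bundle of results and written
    file paths."""
    cfg = _load_config(config)
    outdir = Path(output_dir or cfg.get("output_dir", "twinace_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    stderr = logging.StreamHandler(sys.stderr)
    log.addHandler(stderr)
    bundle = {"outputs": {}, "selection": {}}
    try:
        log.info("config: %s", json.dumps({k: str(v) for k, v in cfg.items()}))
        stage = "load"
        data = _obtain_data(cfg)
        traits = cfg.get("traits") or data.traits
        log.info(
            "data: %d MZ + %d DZ pairs, traits %s",
            data.n_pairs("MZ"), data.n_pairs("DZ"), list(traits),
        )

        stage = "residualize"
        covs = tuple(cfg["covariates"])
        if covs:
            adj, diag = residualize_covariates(data, covs)
            log.info("residual-original correlations: %s", diag)
        else:
            adj, diag = data, {}
        bundle["residual_diagnostics"] = diag

        stage = "phenotypic"
        t1 = table1_report(data)
        t1.to_csv(outdir / "table1.csv")
        bundle["outputs"]["table1"] = str(outdir / "table1.csv")
        cfa = OneFactorCFA.from_dataset(adj, seed=cfg["seed"]).fit()
        pd.DataFrame(
            {
                "trait": list(cfa.traits),
                "loading": cfa.loadings,
                "uniqueness": cfa.uniquenesses,
            }
        ).assign(chi2=cfa.chi2, df=cfa.df, CFI=cfa.cfi, RMSEA=cfa.rmsea,
                 SRMR=cfa.srmr).to_csv(outdir / "cfa.csv", index=False)
        bundle["outputs"]["cfa"] = str(outdir / "cfa.csv")
        bundle["cfa"] = cfa

        stage = "univariate"
        frames = []
        for trait in traits if cfg["univariate_models"] else []:
            table, fits, sat = compare_univariate(
                adj, trait, models=cfg["univariate_models"],
                n_restarts=cfg["n_restarts"], seed=cfg["seed"],
            )
            best = select_model(table, cfg["criterion"])
            log.info("univariate %s: selected %s by %s", trait, best,
                     cfg["criterion"])
            bundle["selection"][trait] = best
            f = table.to_frame()
            f.insert(0, "trait", trait)
            est = pd.DataFrame(
                [
                    {
                        "trait": trait,
                        "model": fit.model,
                        **{f"{c.lower()}2": fit.standardized.get(c, np.nan)
                           for c in ("A", "C", "D", "E")},
                    }
                    for fit in fits
                ]
            )
            frames.append(f.merge(est, on=["trait", "model"]))
        if frames:
            table2 = pd.concat(frames, ignore_index=True)
            table2.to_csv(outdir / "table2.csv", index=False)
            bundle["outputs"]["table2"] = str(outdir / "table2.csv")
            bundle["table2"] = table2

        stage = "multivariate"
        if not cfg["multivariate_structures"]:
            with open(outdir / "selection.json", "w") as fh:
                json.dump(bundle["selection"], fh, indent=2)
            bundle["outputs"]["selection"] = str(outdir / "selection.json")
            return bundle
        mtable, mfits, msat = compare_multivariate(
            adj, traits, structures=cfg["multivariate_structures"],
            components=cfg["components"], n_restarts=cfg["n_restarts"],
            seed=cfg["seed"],
        )
        mtable.write_csv(outdir / "table4.csv")
        bundle["outputs"]["table4"] = str(outdir / "table4.csv")
        bundle["table4"] = mtable
        best_structure = select_model(mtable, cfg["criterion"])
        bundle["selection"]["multivariate"] = best_structure
        log.info("multivariate: selected %s by %s", best_structure,
                 cfg["criterion"])

        by_structure = {f.structure: f for f in mfits}
        if "cholesky" in by_structure:
            sol = by_structure["cholesky"].correlated_factors_solution()
            k = len(traits)
            M = np.full((k, k), np.nan)
            for i in range(k):
                for j in range(k):
                    if i > j and sol.r_g is not None:
                        M[i, j] = sol.r_g[i, j]
                    elif i < j and sol.r_e is not None:
                        M[i, j] = sol.r_e[i, j]
            pd.DataFrame(M, index=list(traits), columns=list(traits)).to_csv(
                outdir / "table3.csv"
            )
            bundle["outputs"]["table3"] = str(outdir / "table3.csv")
            bundle["correlation_solution"] = sol
        if "common_pathway" in by_structure:
            dec = by_structure["common_pathway"].pathway_decomposition()
            frame = dec.to_frame()
            frame["factor_heritability"] = dec.factor_heritability
            frame.to_csv(outdir / "decomposition.csv")
            bundle["outputs"]["decomposition"] = str(outdir / "decomposition.csv")
            bundle["decomposition"] = dec

        with open(outdir / "selection.json", "w") as fh:
            json.dump(bundle["selection"], fh, indent=2)
        bundle["outputs"]["selection"] = str(outdir / "selection.json")
        return bundle
    except StageError:
        raise
    except Exception as err:  # noqa: BLE001 - annotate with stage
        raise StageError(stage, err) from err
    finally:
        log.removeHandler(handler)
        log.removeHandler(stderr)
        handler.close()
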