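"""End-to-end synthetic benchmark: library-sampling ensembles vs single models.

For each seeded aquatic-style scenario the full candidate space is fitted
once on the training year; the *single model* is the best candidate by
validation error (the standard single-model workflow), the *median single
model* is the median test score across all fitted candidates, and the
library-sampling ensemble (k = 10, duplicates allowed, average combining,
validation selection) is served from the same fitted pool via the fast
variant. Scores are test-year ReRMSE.

The default optimizer budget is deliberately small (population 20, 60
objective evaluations per parameter): the candidate space has at most three
free parameters per structure and smooth objectives, for which this budget
reaches workable fits while keeping a multi-scenario benchmark cheap.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ensembles import fit_full_pool, learn_ls_ensemble_fast
from .evaluation import rermse
from .fitting import DEConfig
from .synthetic_data import generate, make_aquatic_style

BENCH_DE = DEConfig(population=20, evals_per_param=60)


def ls_vs_single(
    n_scenarios: int = 10,
    seed: int = 0,
    k: int = 10,
    cfg: DEConfig = BENCH_DE,
    noise_sigma: float = 0.05,
) -> pd.DataFrame:
    """Run the benchmark; one row per scenario.

    Columns: ``single`` (best-on-validation candidate), ``median_single``
    (median test score over all candidates) and ``ensemble`` (k-constituent
    library-sampling ensemble, average combining).
    """
    rows = []
    for i in range(n_scenarios):
        scenario_seed = (seed * 10007 + i) % (2**31)
        lib, sc = make_aquatic_style(seed=scenario_seed, noise_sigma=noise_sigma)
        data = generate(sc, lib)
        run_cfg = DEConfig(
            population=cfg.population,
            evals_per_param=cfg.evals_per_param,
            F=cfg.F,
            Cr=cfg.Cr,
            seed=scenario_seed,
        )
        pool = fit_full_pool(lib, sc.incomplete, data["train"], run_cfg)
        ensemble = learn_ls_ensemble_fast(
            lib,
            data["train"],
            data["validation"],
            sc.incomplete,
            allow_duplicates=True,
            k=k,
            cfg=run_cfg,
            seed=scenario_seed + 1,
            pool=pool,
        )
        test_scores = {
            key: rermse(data["test"], model.simulate(data["test"])) for key, model in pool.items()
        }
        val_scores = {key: m.score(data["validation"]) for key, m in pool.items()}
        best_key = min(sorted(val_scores), key=val_scores.get)
        rows.append(
            {
                "seed": scenario_seed,
                "single": test_scores[best_key],
                "median_single": float(np.median(list(test_scores.values()))),
                "ensemble": rermse(data["test"], ensemble.simulate(data["test"])),
            }
        )
    return pd.DataFrame(rows)
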