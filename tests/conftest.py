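import numpy as np
import pytest

import fattygs as fg


@pytest.fixture(scope="session")
def small_sim():
    """One modest simulated dataset shared across read-only tests."""
    cfg = fg.SimConfig(
        n_individuals=300,
        n_chromosomes=2,
        snps_per_chrom=150,
        n_qtl=3,
        target_h2=0.5,
        seed=3,
    )
    geno = fg.simulate_genotypes(cfg)
    table, truth = fg.simulate_phenotypes(geno, cfg)
    adj = fg.adjust_phenotypes(table, "sim_trait")
    grm = fg.build_grm(geno)
    return {"cfg": cfg, "geno": geno, "table": table, "truth": truth, "adj": adj, "grm": grm}


@pytest.fixture(scope="session")
def small_varcomp(small_sim):
    return fg.reml_univariate(small_sim["adj"], small_sim["grm"])


@pytest.fixture(scope="session")
def small_posterior(small_sim, small_varcomp):
    """A short BayesB chain on the shared dataset."""
    vc = small_varcomp
    cfg = fg.derive_scale_params(
        vc.sigma_a2,
        vc.sigma_e2,
        small_sim["geno"],
        fg.BayesBConfig(pi=0.98, n_iter=2000, burn_in=500, seed=1, gv_thin=5),
    )
    return fg.run_bayesb(small_sim["adj"], small_sim["geno"], cfg)


def adjusted_from(ids, values, name="trait"):
    return fg.AdjustedPhenotype(ids=np.asarray(ids, dtype=object),
                                y_adj=np.asarray(values, dtype=float), trait=name)
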