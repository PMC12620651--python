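import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from crosskit import breeding_sim as bs
from crosskit import fixtures as fx

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")

# keep solver INFO chatter out of test output
logging.getLogger("crosskit").setLevel(logging.ERROR)
logging.getLogger("crosskit.dirdom_model").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_panel():
    """50 x 200 diploid panel with known effects and Eq.-1 phenotypes."""
    spec = fx.FixtureSpec(n_individuals=50, n_markers=200, seed=11)
    G, truth = fx.make_panel(spec)
    pheno, truth = fx.make_phenotypes(G, truth, spec)
    return G, pheno, truth, spec


def reduced_sim_config(mean_dd: float, h2: float) -> bs.SimConfig:
    """The reduced-scale study conditions: n=100, 2 chromosomes, 500 SNPs."""
    return bs.SimConfig(
        n_founders=100,
        n_chromosomes=2,
        sites_per_chr=300,
        markers_per_chr=250,
        n_qtl=56,
        mean_dd=mean_dd,
        var_dd=0.2,
        h2_trait=h2,
        burn_in_cycles=10,
        n_cycles=10,
        n_crosses=20,
        progeny_per_cross=5,
    )


@pytest.fixture(scope="session")
def sim_grid():
    """Five-seed trajectories for a purely additive and an overdominant trait.

    Shared between the burn-in neutrality and heterozygosity-trend checks so
    the simulations run once per session.
    """
    out = {}
    for mean_dd, h2 in ((0.0, 0.6), (2.0, 0.3)):
        frames = []
        for seed in range(1, 6):
            df = bs.run_experiment(reduced_sim_config(mean_dd, h2), seed=seed)
            df.insert(0, "seed", seed)
            frames.append(df)
        out[mean_dd] = pd.concat(frames, ignore_index=True)
    return out


def brute_force_f1_mean(a, d, dos1, dos2):
    """Diploid oracle: enumerate the four gamete combinations per locus.

    Gamete allele probability equals dosage/2; genotype values are
    +a (alt/alt), d (het), -a (ref/ref).  Independent of the closed form.
    """
    a = np.asarray(a, float)
    d = np.asarray(d, float)
    total = 0.0
    for ai, di, k1, k2 in zip(a, d, np.asarray(dos1), np.asarray(dos2)):
        p1, p2 = k1 / 2.0, k2 / 2.0
        pr_aa = p1 * p2
        pr_het = p1 * (1 - p2) + (1 - p1) * p2
        pr_rr = (1 - p1) * (1 - p2)
        total += ai * (pr_aa - pr_rr) + di * pr_het
    return total
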