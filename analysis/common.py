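"""Shared setup for the numbered analysis drivers.

Each driver regenerates the same synthetic cohort from a seed (a few
seconds) rather than passing large genotype files between steps, so every
script is self-contained and exactly reproducible.
"""

import argparse
from pathlib import Path

import mrsurv as m

PCS = ("pc1", "pc2", "pc3", "pc4")


def parser(description: str) -> argparse.ArgumentParser:
    ap = argparse.ArgumentParser(description=description)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n", type=int, default=50_000)
    ap.add_argument("--out", type=Path, default=Path("results"))
    return ap


def scored_cohort(seed: int, n: int, **kw):
    """Default-calibration cohort after exclusions, with both scores."""
    params = m.SimulationParams(n_individuals=n, seed=seed, **kw)
    sim = m.simulate_cohort(params)
    analysis, older, ledger = m.apply_exclusions(sim.table, sim.flags)
    dos = sim.geno.dosages.loc[analysis.index]
    bmi_gs = m.compute_score(dos, sim.panel, "bmi", sim.geno.coded_allele,
                             sim.geno.other_allele)
    diab_gs = m.compute_score(dos, sim.panel, "diab", sim.geno.coded_allele,
                              sim.geno.other_allele)
    analysis = analysis.assign(bmi_score=bmi_gs.std.to_numpy(),
                               diab_score=diab_gs.std.to_numpy())
    return sim, analysis, older, ledger, dos
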