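"""Replicated scenario runs and Monte-Carlo summaries.

One replicate = one simulated dataset (founders, offspring, QTL effects,
phenotypes) evaluated by both BLUP (offspring-block pedigree A) and GBLUP
(VanRaden G), followed by Ne-constrained orchard selection at every target.
Within a replicate both methods and all clonal sizes share the same
genotypes and QTL effects so that method and N_R contrasts are paired; the
master seed is split into named child streams (map / founders / meiosis /
effects / residuals-per-N_R) to guarantee that.

Summaries report per-cell means, standard errors (SD divided by the square
root of the iteration count), paired GBLUP - BLUP differences, and two-sided
paired t-test significance flags at alpha = 0.05.
"""

from __future__ import annotations

import sys
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import GridConfig
from .evaluation import EigenK, accuracy, blup_predict, reml_fit
from .relatedness import ensure_invertible, vanraden_G
from .selection import realized_gain, select_unrelated_topset
from .simpop import (
    FounderConfig,
    MatingDesign,
    build_map,
    make_offspring,
    simulate_founders,
)
from .traits import calibrate_residual_variance, draw_qtl_effects, simulate_phenotypes, true_breeding_values

__all__ = ["Scenario", "ReplicateResult", "run_replicate", "summarize",
           "SummaryTable", "run_cell", "full_grid", "GridResult", "replicate_seed"]

# named child-stream keys of the per-replicate seed (counter-based split)
_STREAM_MAP, _STREAM_FOUNDERS, _STREAM_MEIOSIS, _STREAM_EFFECTS, _STREAM_RESID = range(5)


@dataclass(frozen=True)
class Scenario:
    """One (family size, marker density) cell of the study grid.

    All clonal sizes and Ne targets are evaluated on the same simulated
    dataset per replicate; ``methods`` may drop GBLUP for marker-free runs.
    """

    family_size: int = 80
    marker_density: float = 1.0
    n_ramets: tuple[int, ...] = (1, 6, 12)
    ne_targets: tuple[int, ...] = (5, 10, 20, 25)
    methods: tuple[str, ...] = ("BLUP", "GBLUP")
    n_parents: int = 50
    n_chrom: int = 2
    chrom_length: float = 120.0
    n_qtl: int = 200
    h2: float = 0.2
    freq_min: float = 0.1
    freq_max: float = 0.9
    ld_decay_rate: float | None = None  # None = linkage-equilibrium founders
    qtl_on_markers: bool = False

    def __post_init__(self) -> None:
        if not set(self.methods) <= {"BLUP", "GBLUP"}:
            raise ValueError("methods must be a subset of {'BLUP', 'GBLUP'}")
        if max(self.ne_targets) > self.n_parents // 2:
            raise ValueError("ne_targets exceed the number of full-sib families")

    @property
    def n_families(self) -> int:
        return self.n_parents // 2


@dataclass(frozen=True)
class ReplicateResult:
    """Per-replicate accuracies, standardized gains and variance components,
    keyed by (method, n_r) and (method, n_r, ne)."""

    seed: int
    family_size: int
    marker_density: float
    accuracy: dict
    gain: dict
    varcomp: dict

    def rows(self) -> list[dict]:
        out = []
        base = dict(seed=self.seed, family_size=self.family_size,
                    marker_density=self.marker_density)
        for (m, nr), v in self.accuracy.items():
            out.append(dict(base, method=m, n_r=nr, statistic="accuracy",
                            ne=np.nan, value=v))
        for (m, nr, ne), v in self.gain.items():
            out.append(dict(base, method=m, n_r=nr, statistic="gain",
                            ne=ne, value=v))
        return out


def _child_rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=tuple(key)))


def run_replicate(scenario: Scenario, seed: int) -> ReplicateResult:
    """Simulate one dataset and evaluate every method / N_R / Ne combination.

    Fully deterministic given (scenario, seed).  The relationship matrices
    are eigendecomposed once per replicate and reused across clonal sizes.
    """
    sc = scenario
    gmap = build_map(sc.n_chrom, sc.chrom_length, sc.marker_density, sc.n_qtl,
                     _child_rng(seed, _STREAM_MAP), sc.qtl_on_markers)
    fcfg = FounderConfig(sc.n_parents, sc.freq_min, sc.freq_max, sc.ld_decay_rate)
    founders = simulate_founders(gmap, fcfg, _child_rng(seed, _STREAM_FOUNDERS))
    design = MatingDesign(sc.n_parents, sc.family_size)
    pop = make_offspring(founders, design, gmap, _child_rng(seed, _STREAM_MEIOSIS))

    arch = draw_qtl_effects(sc.n_qtl, sc.h2, _child_rng(seed, _STREAM_EFFECTS))
    tbv = true_breeding_values(pop.offspring_genotypes[:, gmap.qtl_idx], arch.qtl_effects)
    sigma2_e = calibrate_residual_variance(tbv, sc.h2)
    family = pop.offspring_family

    eig = {}
    if "BLUP" in sc.methods:
        eig["BLUP"] = EigenK.from_equal_full_sib_blocks(sc.n_families, sc.family_size)
    if "GBLUP" in sc.methods:
        G = vanraden_G(pop.offspring_genotypes[:, gmap.marker_idx], ids=pop.offspring_ids)
        G = ensure_invertible(G)
        eig["GBLUP"] = EigenK.from_dense(G.values)

    acc: dict = {}
    gain: dict = {}
    vcs: dict = {}
    for n_r in sc.n_ramets:
        phen = simulate_phenotypes(tbv, sigma2_e, n_r, _child_rng(seed, _STREAM_RESID, n_r))
        for method in sc.methods:
            vc = reml_fit(phen.phenotype, eig[method])
            res = blup_predict(phen.phenotype, eig[method], vc, method=method)
            acc[(method, n_r)] = accuracy(res.ebv, tbv)
            vcs[(method, n_r)] = vc
            for ne in sc.ne_targets:
                sel = select_unrelated_topset(res.ebv, family, ne)
                gain[(method, n_r, ne)] = realized_gain(sel, tbv)
    return ReplicateResult(seed, sc.family_size, sc.marker_density, acc, gain, vcs)


def replicate_seed(master_seed: int, family_size: int, marker_density: float, rep: int) -> int:
    """Deterministic per-replicate seed, independent of grid traversal order."""
    ss = np.random.SeedSequence(
        entropy=master_seed,
        spawn_key=(int(family_size), int(round(marker_density * 1000)), int(rep)),
    )
    return int(ss.generate_state(1)[0] % (2**31))


def run_cell(scenario: Scenario, n_iterations: int, master_seed: int,
             progress: bool = False) -> list[ReplicateResult]:
    """Run ``n_iterations`` independent replicates of one scenario cell."""
    reps = []
    for r in range(n_iterations):
        t0 = time.perf_counter()
        seed = replicate_seed(master_seed, scenario.family_size, scenario.marker_density, r)
        reps.append(run_replicate(scenario, seed))
        if progress:
            print(
                f"[cell fam={scenario.family_size} dens={scenario.marker_density}]"
                f" rep {r + 1}/{n_iterations} ({time.perf_counter() - t0:.1f}s)",
                file=sys.stderr,
            )
    return reps


# ---------------------------------------------------------------------------
# summaries


@dataclass(frozen=True)
class SummaryTable:
    """Monte-Carlo summary of one scenario cell.

    ``accuracy``: per (method, n_r) mean / se / n.
    ``gains``: per (method, n_r, ne) mean / se.
    ``gain_differences``: paired GBLUP - BLUP gain per (n_r, ne) with
    two-sided paired-t significance at alpha = 0.05.
    ``accuracy_ratio``: 100 * mean GBLUP / mean BLUP accuracy per n_r.
    """

    accuracy: pd.DataFrame
    gains: pd.DataFrame
    gain_differences: pd.DataFrame
    accuracy_ratio: pd.DataFrame
    n_iterations: int


def _mean_se(x: np.ndarray) -> tuple[float, float]:
    x = np.asarray(x, float)
    return float(x.mean()), float(x.std(ddof=1) / np.sqrt(x.size))


def summarize(replicates: list[ReplicateResult], alpha: float = 0.05) -> SummaryTable:
    """Aggregate replicates: means, SE = SD/sqrt(n), paired method contrasts."""
    n = len(replicates)
    if n < 2:
        raise ValueError("need at least 2 replicates to summarize")

    acc_rows = []
    for key in replicates[0].accuracy:
        vals = np.array([r.accuracy[key] for r in replicates])
        m, se = _mean_se(vals)
        acc_rows.append(dict(method=key[0], n_r=key[1], mean=m, se=se, n=n))
    acc = pd.DataFrame(acc_rows).set_index(["method", "n_r"]).sort_index()

    gain_rows = []
    for key in replicates[0].gain:
        vals = np.array([r.gain[key] for r in replicates])
        m, se = _mean_se(vals)
        gain_rows.append(dict(method=key[0], n_r=key[1], ne=key[2], mean=m, se=se, n=n))
    gains = pd.DataFrame(gain_rows).set_index(["method", "n_r", "ne"]).sort_index()

    methods = {k[0] for k in replicates[0].accuracy}
    diff_rows, ratio_rows = [], []
    if {"BLUP", "GBLUP"} <= methods:
        for key in replicates[0].gain:
            if key[0] != "GBLUP":
                continue
            _, nr, ne = key
            g = np.array([r.gain[("GBLUP", nr, ne)] for r in replicates])
            b = np.array([r.gain[("BLUP", nr, ne)] for r in replicates])
            d = g - b
            m, se = _mean_se(d)
            if se == 0.0:  # degenerate: identical paired differences
                t, p = 0.0, (1.0 if m == 0 else 0.0)
            else:
                t, p = stats.ttest_rel(g, b)
            diff_rows.append(dict(n_r=nr, ne=ne, mean=m, se=se,
                                  t=float(t), p=float(p), significant=bool(p < alpha)))
        for nr in sorted({k[1] for k in replicates[0].accuracy}):
            g = np.array([r.accuracy[("GBLUP", nr)] for r in replicates])
            b = np.array([r.accuracy[("BLUP", nr)] for r in replicates])
            ratio_rows.append(dict(n_r=nr, ratio_pct=100.0 * g.mean() / b.mean()))
    diffs = (pd.DataFrame(diff_rows).set_index(["n_r", "ne"]).sort_index()
             if diff_rows else pd.DataFrame())
    ratios = pd.DataFrame(ratio_rows).set_index("n_r") if ratio_rows else pd.DataFrame()
    return SummaryTable(acc, gains, diffs, ratios, n)


# ---------------------------------------------------------------------------
# full grid


@dataclass(frozen=True)
class GridResult:
    """Tidy per-replicate results plus wide study-style tables."""

    replicates: pd.DataFrame  # long format
    accuracy_table: pd.DataFrame  # rows density, cols (family, n_r, method)
    accuracy_se_table: pd.DataFrame
    gain_difference_table: pd.DataFrame  # rows density, cols (family, n_r, ne)
    gain_significance_table: pd.DataFrame
    gain_table: pd.DataFrame  # standardized gains, rows density
    accuracy_ratio_table: pd.DataFrame  # GBLUP/BLUP %, rows density
    config: GridConfig


def _scenario_for(config: GridConfig, family_size: int, density: float) -> Scenario:
    return Scenario(
        family_size=family_size,
        marker_density=density,
        n_ramets=config.n_ramets,
        ne_targets=config.ne_targets,
        n_parents=config.n_parents,
        n_chrom=config.n_chrom,
        chrom_length=config.chrom_length,
        n_qtl=config.n_qtl,
        h2=config.h2,
        freq_min=config.freq_min,
        freq_max=config.freq_max,
        ld_decay_rate=config.ld_decay_rate,
        qtl_on_markers=config.qtl_on_markers,
    )


def full_grid(config: GridConfig, n_iterations: int | None = None,
              progress: bool = False) -> GridResult:
    """Run every (family size, marker density) cell of the grid and build
    accuracy and gain-difference tables in the study layout."""
    n_it = config.n_iterations if n_iterations is None else n_iterations
    long_rows = []
    acc_cells, acc_se_cells, diff_cells, sig_cells, gain_cells, ratio_cells = ({} for _ in range(6))
    for fam in config.family_sizes:
        for dens in config.marker_densities:
            sc = _scenario_for(config, fam, dens)
            reps = run_cell(sc, n_it, config.seed, progress=progress)
            for r in reps:
                long_rows.extend(r.rows())
            summ = summarize(reps)
            for (method, nr), row in summ.accuracy.iterrows():
                acc_cells[(dens, (fam, nr, method))] = row["mean"]
                acc_se_cells[(dens, (fam, nr, method))] = row["se"]
            for (nr, ne), row in summ.gain_differences.iterrows():
                diff_cells[(dens, (fam, nr, ne))] = row["mean"]
                sig_cells[(dens, (fam, nr, ne))] = row["significant"]
            for (method, nr, ne), row in summ.gains.iterrows():
                gain_cells[(dens, (fam, method, nr, ne))] = row["mean"]
            for nr, row in summ.accuracy_ratio.iterrows():
                ratio_cells[(dens, (fam, nr))] = row["ratio_pct"]

    def _wide(cells: dict, names: list[str]) -> pd.DataFrame:
        if not cells:
            return pd.DataFrame()
        ser = pd.Series(cells)
        df = ser.unstack(level=0).T
        df.index.name = "marker_density"
        df.columns = pd.MultiIndex.from_tuples(df.columns, names=names)
        return df.sort_index(axis=1)

    return GridResult(
        replicates=pd.DataFrame(long_rows),
        accuracy_table=_wide(acc_cells, ["family_size", "n_r", "method"]),
        accuracy_se_table=_wide(acc_se_cells, ["family_size", "n_r", "method"]),
        gain_difference_table=_wide(diff_cells, ["family_size", "n_r", "ne"]),
        gain_significance_table=_wide(sig_cells, ["family_size", "n_r", "ne"]),
        gain_table=_wide(gain_cells, ["family_size", "method", "n_r", "ne"]),
        accuracy_ratio_table=_wide(ratio_cells, ["family_size", "n_r"]),
        config=config,
    )
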