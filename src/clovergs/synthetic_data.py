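"""Simulation of half-sib breeding populations, GBS reads and trial phenotypes.

The generator emulates the study conditions of an outcrossing half-sib (HS)
family forage programme: maternal parents genotyped at biallelic SNPs, each
HS family produced by one recorded maternal gamete plus a gamete drawn from
an open-pollination pollen pool over all parents (selfing excluded), traits
controlled by a set of pleiotropic QTL with a target genetic correlation
structure, and plot-level phenotypes from a replicated multi-location,
multi-year trial that includes repeated check-cultivar plots.

Sequencing is modelled as negative-binomial (gamma–Poisson) read depth per
entry with binomial allele sampling given the true dosage — the read model
under which the depth-adjusted kinship estimator is unbiased.  Markers are
unlinked (free recombination); no sequencing error unless requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from clovergs.genotype_qc import MISSING, GenotypeData

DEFAULT_VAR_COMPONENTS = {
    "sigma2_f": 1.0,
    "sigma2_fl": 0.6,
    "sigma2_fy": 0.6,
    "sigma2_e": 2.0,
}


@dataclass
class SimConfig:
    """Study conditions for the simulated breeding programme.

    Defaults mirror the trial design the analysis assumes: 200 HS families,
    two locations, three years, three replicates, 24 check plots per
    replicate (12 per check cultivar), 100 seedlings established per family.
    ``mean_depth``/``depth_dispersion`` give low-coverage GBS with a median
    read depth well under 12.8.

    ``var_components`` is a list of per-trait dicts with keys sigma2_f,
    sigma2_fl, sigma2_fy, sigma2_e.  When ``h2_family_mean`` is supplied,
    sigma2_f is re-derived per trait so the family-mean heritability of the
    evaluation design hits that target.
    """

    n_families: int = 200
    seedlings_per_family: int = 100
    n_markers: int = 2000
    n_founder_lines: int | None = 40
    maf_range: tuple[float, float] = (0.05, 0.5)
    mean_depth: float = 8.0
    depth_dispersion: float | None = 2.0  # NB size; None = Poisson
    read_error_rate: float = 0.0
    n_locations: int = 2
    n_years: int = 3
    n_reps: int = 3
    n_checks_per_rep: int = 24
    n_qtl: int | None = None  # default: min(100, n_markers)
    h2_family_mean: list[float] | None = None
    var_components: list[dict] = field(
        default_factory=lambda: [dict(DEFAULT_VAR_COMPONENTS)]
    )
    genetic_correlation: np.ndarray | None = None
    grand_mean: float = 10.0
    fixed_effect_sd: float = 1.0
    seed: int = 0

    @property
    def n_traits(self) -> int:
        return len(self.var_components)

    @property
    def resolved_n_qtl(self) -> int:
        return self.n_qtl if self.n_qtl is not None else min(100, self.n_markers)

    def trait_names(self) -> list[str]:
        return [f"trait{t + 1}" for t in range(self.n_traits)]

    def validate(self) -> None:
        for name in (
            "n_families",
            "seedlings_per_family",
            "n_markers",
            "n_locations",
            "n_years",
            "n_reps",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_checks_per_rep < 0:
            raise ValueError("n_checks_per_rep must be >= 0")
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be >= 0")
        if self.depth_dispersion is not None and self.depth_dispersion <= 0:
            raise ValueError("depth_dispersion must be > 0")
        if not (0 <= self.read_error_rate < 0.5):
            raise ValueError("read_error_rate must be in [0, 0.5)")
        if self.n_qtl is not None and not (1 <= self.n_qtl <= self.n_markers):
            raise ValueError("n_qtl must be in [1, n_markers]")
        for vc in self.var_components:
            for key in ("sigma2_f", "sigma2_fl", "sigma2_fy", "sigma2_e"):
                if vc[key] < 0:
                    raise ValueError(f"variance component {key} must be >= 0")
        rg = self.correlation_matrix()
        if not np.allclose(rg, rg.T):
            raise ValueError("genetic_correlation must be symmetric")
        if not np.allclose(np.diag(rg), 1.0):
            raise ValueError("genetic_correlation must have unit diagonal")
        if np.linalg.eigvalsh(rg).min() < -1e-8:
            raise ValueError("genetic_correlation must be positive semidefinite")
        if self.h2_family_mean is not None:
            if len(self.h2_family_mean) != self.n_traits:
                raise ValueError("h2_family_mean needs one value per trait")
            for h2, vc in zip(self.h2_family_mean, self.var_components):
                if not (0 < h2 <= 1):
                    raise ValueError("h2_family_mean must be in (0, 1]")
                noise = (
                    vc["sigma2_fl"] / self.n_locations
                    + vc["sigma2_fy"] / self.n_years
                    + vc["sigma2_e"]
                    / (self.n_locations * self.n_years * self.n_reps)
                )
                if h2 == 1.0 and noise > 0:
                    raise ValueError(
                        "h2_family_mean = 1 requires zero non-family variance"
                    )

    def correlation_matrix(self) -> np.ndarray:
        if self.genetic_correlation is None:
            return np.eye(self.n_traits)
        return np.asarray(self.genetic_correlation, dtype=float)

    def resolved_var_components(self) -> list[dict]:
        """Per-trait components with sigma2_f re-derived from h2 targets."""
        out = [dict(vc) for vc in self.var_components]
        if self.h2_family_mean is None:
            return out
        for h2, vc in zip(self.h2_family_mean, out):
            noise = (
                vc["sigma2_fl"] / self.n_locations
                + vc["sigma2_fy"] / self.n_years
                + vc["sigma2_e"] / (self.n_locations * self.n_years * self.n_reps)
            )
            if h2 == 1.0:
                vc["sigma2_f"] = vc["sigma2_f"] if vc["sigma2_f"] > 0 else 1.0
            else:
                vc["sigma2_f"] = h2 * noise / (1 - h2)
                if vc["sigma2_f"] == 0:
                    raise ValueError(
                        "infeasible target: zero noise with h2 < 1 gives no "
                        "family variance scale"
                    )
        return out


@dataclass
class TruePopulation:
    """Simulated truth: genotypes, QTL effects and breeding values.

    ``parent_genotypes`` is families × markers (the genotyped maternal
    parents); ``progeny_genotypes`` is (families·seedlings) × markers with
    ``progeny_family`` giving each seedling's family index.  Breeding values
    are centred per trait.
    """

    parent_genotypes: np.ndarray
    progeny_genotypes: np.ndarray
    progeny_family: np.ndarray
    parent_tbv: np.ndarray  # families × traits
    progeny_tbv: np.ndarray  # seedlings × traits
    qtl_effects: np.ndarray  # markers × traits (zero off-QTL)
    allele_freqs: np.ndarray
    family_ids: list[str]
    config: SimConfig

    @property
    def family_mean_tbv(self) -> np.ndarray:
        """families × traits mean of seedling breeding values."""
        n_fam = len(self.family_ids)
        out = np.zeros((n_fam, self.progeny_tbv.shape[1]))
        for f in range(n_fam):
            out[f] = self.progeny_tbv[self.progeny_family == f].mean(axis=0)
        return out


def _gametes(genotypes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One random gamete per individual: Bernoulli(dosage/2) per marker."""
    return (rng.random(genotypes.shape) < genotypes / 2.0).astype(np.int8)


def simulate_population(config: SimConfig) -> TruePopulation:
    """Simulate founder parents, HS progeny and true breeding values.

    Founder allele frequencies are uniform on ``maf_range`` and parents are
    in Hardy–Weinberg proportions.  Each seedling receives one maternal
    gamete (free recombination) and one pollen-pool gamete from a random
    non-self parent.  QTL effects are multivariate normal across traits with
    the requested genetic correlation and are rescaled per trait so that the
    variance of family-mean breeding values equals sigma2_f exactly.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_fam, n_seed, m = config.n_families, config.seedlings_per_family, config.n_markers

    p = rng.uniform(*config.maf_range, size=m)
    if config.n_founder_lines is None:
        # mutually unrelated parents in exact Hardy-Weinberg proportions
        parents = (
            (rng.random((n_fam, m)) < p).astype(np.int8)
            + (rng.random((n_fam, m)) < p).astype(np.int8)
        )
    else:
        # parents are crosses among a limited founder-line base, giving the
        # sib structure of real breeding material; prediction accuracy in
        # such panels is largely relatedness-driven
        n_lines = config.n_founder_lines
        if n_lines < 2:
            raise ValueError("n_founder_lines must be >= 2")
        lines = (
            (rng.random((n_lines, m)) < p).astype(np.int8)
            + (rng.random((n_lines, m)) < p).astype(np.int8)
        )
        dam = rng.integers(0, n_lines, n_fam)
        sire = (dam + rng.integers(1, n_lines, n_fam)) % n_lines  # no selfing
        parents = _gametes(lines[dam], rng) + _gametes(lines[sire], rng)

    progeny = np.empty((n_fam * n_seed, m), dtype=np.int8)
    prog_family = np.repeat(np.arange(n_fam), n_seed)
    for f in range(n_fam):
        maternal = _gametes(np.broadcast_to(parents[f], (n_seed, m)), rng)
        fathers = rng.integers(0, n_fam - 1, size=n_seed)
        fathers[fathers >= f] += 1  # selfing excluded
        paternal = _gametes(parents[fathers], rng)
        progeny[f * n_seed : (f + 1) * n_seed] = maternal + paternal

    # pleiotropic QTL with correlated effects
    n_qtl = config.resolved_n_qtl
    qtl_idx = rng.choice(m, size=n_qtl, replace=False)
    chol = np.linalg.cholesky(
        config.correlation_matrix() + 1e-10 * np.eye(config.n_traits)
    )
    raw = rng.standard_normal((n_qtl, config.n_traits)) @ chol.T
    if config.n_traits > 1:
        # recolour the effects so the realized progeny breeding values carry
        # the target correlation exactly (finite QTL draws are noisy)
        t_raw = (progeny[:, qtl_idx].astype(float) - 2 * p[qtl_idx]) @ raw
        C_t = np.cov(t_raw, rowvar=False)
        L_c = np.linalg.cholesky(C_t + 1e-10 * np.eye(config.n_traits))
        raw = raw @ np.linalg.inv(L_c).T @ chol.T
    effects = np.zeros((m, config.n_traits))
    effects[qtl_idx] = raw

    centred_prog = progeny[:, qtl_idx].astype(float) - 2 * p[qtl_idx]
    tbv_prog = centred_prog @ raw
    centred_par = parents[:, qtl_idx].astype(float) - 2 * p[qtl_idx]
    tbv_par = centred_par @ raw

    # scale so the family-mean variance matches sigma2_f per trait
    vcs = config.resolved_var_components()
    fam_means = np.vstack(
        [tbv_prog[prog_family == f].mean(axis=0) for f in range(n_fam)]
    )
    for t in range(config.n_traits):
        target = vcs[t]["sigma2_f"]
        observed = fam_means[:, t].var(ddof=1)
        if observed <= 0:
            raise ValueError("degenerate QTL sampling: no family-mean variance")
        s = np.sqrt(target / observed)
        tbv_prog[:, t] *= s
        tbv_par[:, t] *= s
        effects[:, t] *= s
    tbv_par -= tbv_prog.mean(axis=0)
    tbv_prog -= tbv_prog.mean(axis=0)

    family_ids = [f"F{f + 1:03d}" for f in range(n_fam)]
    return TruePopulation(
        parent_genotypes=parents,
        progeny_genotypes=progeny,
        progeny_family=prog_family,
        parent_tbv=tbv_par,
        progeny_tbv=tbv_prog,
        qtl_effects=effects,
        allele_freqs=p,
        family_ids=family_ids,
        config=config,
    )


def simulate_gbs_reads(
    pop_or_dosage,
    mean_depth: float,
    depth_dispersion: float | None = 2.0,
    seed: int = 0,
    read_error_rate: float = 0.0,
    sample_ids: list[str] | None = None,
) -> GenotypeData:
    """Sample GBS reads over true dosages and return called genotypes.

    Depth per entry is negative binomial with the given mean and dispersion
    (gamma–Poisson mixture; ``depth_dispersion=None`` gives Poisson).  Given
    depth k, alternate-allele reads are Binomial(k, dosage/2); a depth-0
    entry is a missing call.  The naive call is 0/2 when only one allele is
    seen and 1 otherwise, so a true heterozygote at depth k is miscalled
    homozygous with probability 2·(1/2)^k.
    """
    if mean_depth < 0:
        raise ValueError("mean_depth must be >= 0")
    if depth_dispersion is not None and depth_dispersion <= 0:
        raise ValueError("depth_dispersion must be > 0")
    if isinstance(pop_or_dosage, TruePopulation):
        dosage = pop_or_dosage.parent_genotypes
        if sample_ids is None:
            sample_ids = list(pop_or_dosage.family_ids)
    else:
        dosage = np.asarray(pop_or_dosage)
    if not np.isin(dosage, [0, 1, 2]).all():
        raise ValueError("true dosages must be in {0, 1, 2}")
    n, m = dosage.shape
    rng = np.random.default_rng(seed)

    if depth_dispersion is None:
        depth = rng.poisson(mean_depth, size=(n, m))
    else:
        lam = rng.gamma(depth_dispersion, mean_depth / depth_dispersion, size=(n, m))
        depth = rng.poisson(lam)

    p_alt = dosage / 2.0
    if read_error_rate:
        p_alt = p_alt * (1 - read_error_rate) + (1 - p_alt) * read_error_rate
    alt = rng.binomial(depth, p_alt)
    ref = depth - alt

    calls = np.full((n, m), 1, dtype=np.int8)
    calls[alt == 0] = 0
    calls[alt == depth] = 2
    calls[(alt > 0) & (alt < depth)] = 1
    calls[depth == 0] = MISSING

    if sample_ids is None:
        sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    info = pd.DataFrame(
        {
            "id": [f"M{j + 1:06d}" for j in range(m)],
            "chrom": "chr1",
            "pos": np.arange(1, m + 1) * 100,
            "ref": "A",
            "alt": "C",
        }
    )
    return GenotypeData(
        dosage=calls,
        ref_reads=ref,
        alt_reads=alt,
        marker_info=info,
        sample_ids=list(sample_ids),
        has_depth=True,
    )


CHECK_IDS = ("checkA", "checkB")


def n_plots_per_location(config: SimConfig) -> int:
    return config.n_reps * (config.n_families + config.n_checks_per_rep)


def simulate_trial_phenotypes(
    pop: TruePopulation, config: SimConfig | None = None, seed: int = 1
) -> pd.DataFrame:
    """Plot-level phenotypes for the replicated multi-site, multi-year trial.

    Each plot record is ``y = mu + location + year + rep(location) + f + fl
    + fy + eps`` where ``f`` is the family-mean true breeding value and
    ``fl``, ``fy``, ``eps`` are drawn from the configured variance
    components.  Check plots (two fixed cultivars, half of
    ``n_checks_per_rep`` each) carry fixed cultivar effects but no family
    variance.  Returns a tidy long table with columns entry_id, entry_type,
    location, year, rep, row, col, trait, value.
    """
    config = config or pop.config
    if config.n_families != len(pop.family_ids):
        raise ValueError("population families do not match config")
    rng = np.random.default_rng(seed)
    vcs = config.resolved_var_components()
    traits = config.trait_names()
    n_fam, n_loc, n_yr, n_rep = (
        config.n_families,
        config.n_locations,
        config.n_years,
        config.n_reps,
    )

    loc_eff = rng.normal(0, config.fixed_effect_sd, n_loc)
    yr_eff = rng.normal(0, config.fixed_effect_sd, n_yr)
    rep_eff = rng.normal(0, config.fixed_effect_sd / 2, (n_loc, n_rep))
    # two fixed check cultivars, deterministic offsets on the family scale
    check_eff = {
        trait: np.array([0.5, -0.5]) * np.sqrt(vcs[t]["sigma2_f"])
        for t, trait in enumerate(traits)
    }

    fam_tbv = pop.family_mean_tbv
    fl = {
        trait: rng.normal(0, np.sqrt(vcs[t]["sigma2_fl"]), (n_fam, n_loc))
        for t, trait in enumerate(traits)
    }
    fy = {
        trait: rng.normal(0, np.sqrt(vcs[t]["sigma2_fy"]), (n_fam, n_yr))
        for t, trait in enumerate(traits)
    }

    n_cols = 24
    records = []
    for il in range(n_loc):
        # fixed physical layout per location: entries randomised within rep
        plot_entries = []
        for ir in range(n_rep):
            entries = [("family", f) for f in range(n_fam)]
            for ic in range(config.n_checks_per_rep):
                entries.append(("check", ic % len(CHECK_IDS)))
            order = rng.permutation(len(entries))
            plot_entries.extend((ir, *entries[k]) for k in order)
        for plot_idx, (ir, etype, eidx) in enumerate(plot_entries):
            row, col = divmod(plot_idx, n_cols)
            for iy in range(n_yr):
                base = (
                    config.grand_mean + loc_eff[il] + yr_eff[iy] + rep_eff[il, ir]
                )
                for t, trait in enumerate(traits):
                    eps = rng.normal(0, np.sqrt(vcs[t]["sigma2_e"]))
                    if etype == "family":
                        val = (
                            base
                            + fam_tbv[eidx, t]
                            + fl[trait][eidx, il]
                            + fy[trait][eidx, iy]
                            + eps
                        )
                        eid = pop.family_ids[eidx]
                    else:
                        val = base + check_eff[trait][eidx] + eps
                        eid = CHECK_IDS[eidx]
                    records.append(
                        (eid, etype, f"loc{il + 1}", f"year{iy + 1}",
                         f"rep{ir + 1}", row, col, trait, val)
                    )
    return pd.DataFrame(
        records,
        columns=[
            "entry_id", "entry_type", "location", "year", "rep",
            "row", "col", "trait", "value",
        ],
    )


def write_truth_csv(pop: TruePopulation, path) -> None:
    """Write family-level true breeding values as CSV."""
    df = pd.DataFrame(
        pop.family_mean_tbv,
        index=pd.Index(pop.family_ids, name="family_id"),
        columns=pop.config.trait_names(),
    )
    df.insert(0, "parent_tbv_trait1", pop.parent_tbv[:, 0])
    df.to_csv(path)
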