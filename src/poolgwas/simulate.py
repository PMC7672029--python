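"""Synthetic pooled-frequency panels with planted truth.

The generator emulates the statistical structure of a pooled-DNA hemp
accession panel: a structured population of accessions assigned to
subpopulations whose allele frequencies follow the Balding-Nichols
construction at a configured FST; per accession, a pool of diploid plants
whose haplotypes share a block-copy latent structure so that markers within
an LD block are strongly correlated and markers in different blocks are
nearly independent; pooled allele frequencies observed either exactly or
through Poisson-depth binomial read sampling; and multi-location phenology
with planted QTLs, a polygenic term with kinship covariance, configurable
heritability and between-location genetic correlation.

Flowering genetic values are expressed in degree-days and inverted through
each location's temperature accumulation into calendar dates, so the
phenology module recovers them (up to one-day quantisation) from the
simulated plot records. Sex determination is a latent liability cut at
+/- 1 SD into the plot scores {1, 2, 3}.

Randomness is organised as one child RNG stream per purpose
(genotypes / temperatures / phenotypes), spawned deterministically from the
configured seed, so e.g. adding markers does not perturb the phenotypes.
"""

from __future__ import annotations

import datetime as dt
import zlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import phenology
from .config import SimConfig, PlantedQTL, TRAITS
from .phenology import TemperatureSeries, PlotPhenologyRecord
from .qc import GenotypeMatrix, compute_kinship

NUCLEOTIDES = np.array(list("ACGT"))

_GENO_STREAM, _TEMP_STREAM, _PHENO_STREAM = 0, 1, 2

#: minimum full-flowering gap above begin flowering, degree-days
MIN_FULL_GAP_CD = 10.0


def _stream(seed: int, which: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(which,)))


@dataclass
class ResolvedQTL:
    marker_id: str
    trait: str
    variance_fraction: float
    shared_across_locations: bool
    #: location -> signed effect on the 0-2 dosage scale (unit trait scale)
    effects: dict[str, float] = field(default_factory=dict)


@dataclass
class TruthRecord:
    """Ground truth behind a simulated panel."""

    accessions: list[str]
    marker_ids: list[str]
    subpop: np.ndarray  # per-accession subpopulation label
    true_freqs: np.ndarray  # noise-free pooled major-allele proportions
    #: per-plant dosages of the (pre-orientation) reference allele, for
    #: individual-based estimators such as Weir-Cockerham FST
    individual_genotypes: np.ndarray
    pool_size: int
    qtls: list[ResolvedQTL] = field(default_factory=list)
    #: (trait, location) -> per-accession genetic value on the trait scale
    genetic_values: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    #: (trait, location) -> {"qtl", "polygenic", "noise_accession_mean"}
    #: variance components on the unit trait scale
    variance_decomposition: dict[tuple[str, str], dict[str, float]] = field(
        default_factory=dict
    )

    def realized_h2(self, trait: str, location: str) -> float:
        vd = self.variance_decomposition[(trait, location)]
        g = vd["qtl"] + vd["polygenic"]
        return g / (g + vd["noise_accession_mean"])


def simulate_panel(config: SimConfig) -> tuple[GenotypeMatrix, TruthRecord]:
    """Generate the pooled-frequency genotype panel and its truth record."""
    rng = _stream(config.seed, _GENO_STREAM)
    n_acc, n_sub = config.n_accessions, config.n_subpops
    lo, hi = config.markers_per_scaffold

    # marker layout: scaffolds with a random number of markers at random
    # positions; LD blocks are ld_block_length windows within a scaffold
    scaffold_ids, positions, block_keys = [], [], []
    for k in range(config.n_scaffolds):
        m_k = int(rng.integers(lo, hi + 1))
        span = max(m_k * config.marker_spacing * 2, m_k + 1)
        pos = np.sort(rng.choice(np.arange(1, span + 1), size=m_k, replace=False))
        for p in pos:
            scaffold_ids.append(f"scaffold{k + 1}")
            positions.append(int(p))
            block_keys.append((k, int(p) // config.ld_block_length))
    n_markers = len(positions)
    marker_ids = [f"{s}_{p}" for s, p in zip(scaffold_ids, positions)]

    # Balding-Nichols subpopulation frequencies, drawn at the LD-block level
    # (markers of a block share the block's base frequency up to a small
    # per-marker jitter, so blocks stay coherent within and across
    # subpopulations and within-block LD is strong)
    block_list = sorted(set(block_keys))
    block_index = {b: i for i, b in enumerate(block_list)}
    marker_block = np.array([block_index[b] for b in block_keys])
    n_blocks = len(block_list)
    p_anc_block = rng.uniform(0.1, 0.9, size=n_blocks)
    if config.fst == 0.0:
        p_sub_block = np.tile(p_anc_block, (n_sub, 1))
    else:
        f = config.fst
        a = p_anc_block * (1.0 - f) / f
        b = (1.0 - p_anc_block) * (1.0 - f) / f
        p_sub_block = rng.beta(a, b, size=(n_sub, n_blocks))
    jitter = rng.normal(0.0, 0.05, size=n_markers)

    # accession-level drift: every accession is itself a differentiated
    # population (a cultivar/landrace) whose frequencies drift around its
    # subpopulation's by a second Balding-Nichols step at accession_fst
    subpop = np.arange(n_acc) % n_sub
    if config.accession_fst == 0.0:
        p_acc_block = p_sub_block[subpop]
    else:
        fa = config.accession_fst
        base = np.clip(p_sub_block[subpop], 1e-6, 1.0 - 1e-6)
        p_acc_block = rng.beta(
            base * (1.0 - fa) / fa, (1.0 - base) * (1.0 - fa) / fa
        )
    p_acc = np.clip(p_acc_block[:, marker_block] + jitter[None, :], 0.02, 0.98)

    n_hap_per_acc = 2 * config.pool_size
    n_hap = n_acc * n_hap_per_acc

    # block-copy latent haplotypes: one latent uniform per (haplotype, block)
    # shared by all markers of the block (comonotone coupling -> high |r|),
    # plus a per-marker mutation that re-draws the allele independently;
    # generated block-wise to keep memory proportional to the block size
    alleles = np.empty((n_hap, n_markers), dtype=bool)
    blocks: dict[tuple[int, int], list[int]] = {}
    for j, key in enumerate(block_keys):
        blocks.setdefault(key, []).append(j)
    for key in sorted(blocks):
        idx = np.array(blocks[key])
        pb = np.repeat(p_acc[:, idx], n_hap_per_acc, axis=0)  # (n_hap, m_b)
        u = rng.uniform(size=(n_hap, 1))
        drawn = u < pb
        mut = rng.uniform(size=pb.shape) < config.mutation_prob
        redraw = rng.uniform(size=pb.shape) < pb
        alleles[:, idx] = np.where(mut, redraw, drawn)

    hap3 = alleles.reshape(n_acc, n_hap_per_acc, n_markers)
    true_freq = hap3.mean(axis=1)
    indiv = hap3.reshape(n_acc, config.pool_size, 2, n_markers).sum(axis=2)
    indiv = indiv.reshape(n_acc * config.pool_size, n_markers).astype(np.int8)

    if config.read_depth is None:
        observed = true_freq.copy()
    else:
        depth = np.maximum(rng.poisson(config.read_depth, size=true_freq.shape), 1)
        reads = rng.binomial(depth, true_freq)
        observed = reads / depth

    # orient every marker to the panel-major allele
    flip = observed.mean(axis=0) < 0.5
    observed[:, flip] = 1.0 - observed[:, flip]
    true_oriented = true_freq.copy()
    true_oriented[:, flip] = 1.0 - true_oriented[:, flip]

    allele_pairs = np.array(
        [rng.choice(4, size=2, replace=False) for _ in range(n_markers)]
    )
    markers = pd.DataFrame(
        {
            "marker_id": marker_ids,
            "scaffold": scaffold_ids,
            "position": positions,
            "major": NUCLEOTIDES[allele_pairs[:, 0]],
            "minor": NUCLEOTIDES[allele_pairs[:, 1]],
        }
    )
    accessions = [f"acc{i + 1:03d}" for i in range(n_acc)]
    g = GenotypeMatrix(accessions, markers, observed)

    truth = TruthRecord(
        accessions=accessions,
        marker_ids=marker_ids,
        subpop=subpop,
        true_freqs=true_oriented,
        individual_genotypes=indiv,
        pool_size=config.pool_size,
    )
    truth.qtls = _resolve_planted_qtls(config, truth, rng)
    return g, truth


def _resolve_planted_qtls(
    config: SimConfig, truth: TruthRecord, rng: np.random.Generator
) -> list[ResolvedQTL]:
    """Attach planted QTLs to concrete markers.

    Explicit marker ids are honoured; unspecified ones are drawn from
    markers polymorphic enough to survive SNP selection (true-frequency SD
    >= 0.12, mean in [0.05, 0.95]) whose variation segregates within the
    population structure rather than along it (between-subpopulation share
    of the frequency variance <= 0.25), at most one per scaffold. Causal
    variation aligned with the structure axis is absorbed by the kinship
    correction by design, so planting there would test nothing but the
    correction itself."""
    if not config.planted_qtls:
        return []
    ids = truth.marker_ids
    col = {m: i for i, m in enumerate(ids)}
    sd = truth.true_freqs.std(axis=0)
    mean = truth.true_freqs.mean(axis=0)
    total_var = truth.true_freqs.var(axis=0)
    sub_means = np.stack(
        [truth.true_freqs[truth.subpop == s].mean(axis=0)
         for s in np.unique(truth.subpop)]
    )
    counts = np.array([(truth.subpop == s).sum() for s in np.unique(truth.subpop)])
    grand = truth.true_freqs.mean(axis=0)
    between_var = (counts[:, None] * (sub_means - grand) ** 2).sum(axis=0) / len(
        truth.accessions
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        structural_share = np.where(total_var > 0, between_var / total_var, 1.0)
    eligible = np.flatnonzero(
        (sd >= 0.12) & (mean >= 0.05) & (mean <= 0.95) & (structural_share <= 0.25)
    )
    taken_scaffolds = set()
    resolved = []
    for q in config.planted_qtls:
        if q.marker_id is not None:
            if q.marker_id not in col:
                raise ValueError(f"planted QTL marker {q.marker_id} not generated")
            j = col[q.marker_id]
        else:
            pool = [
                j for j in eligible
                if ids[j].rsplit("_", 1)[0] not in taken_scaffolds
            ]
            if not pool:
                raise ValueError("no eligible markers left for planted QTLs")
            j = int(rng.choice(pool))
        taken_scaffolds.add(ids[j].rsplit("_", 1)[0])
        resolved.append(
            ResolvedQTL(
                marker_id=ids[j],
                trait=q.trait,
                variance_fraction=q.variance_fraction,
                shared_across_locations=q.shared_across_locations,
            )
        )
    return resolved


@dataclass
class LocationParams:
    """Seasonal sinusoid parameters of one trial location."""

    location_id: str
    start_date: dt.date
    n_days: int = 185
    mean_c: float = 16.0
    amplitude_c: float = 6.0
    noise_sd_c: float = 2.0
    peak_doy: int = 200  # day of year of the seasonal temperature peak


def default_locations(n_locations: int, year: int = 2013) -> list[LocationParams]:
    """Three-location template with contrasting mean temperatures (warm
    southern, intermediate, cool northern trial), cycled beyond three."""
    base = [
        ("CRA", 18.0), ("FNPC", 16.0), ("VDS", 14.5),
    ]
    out = []
    for i in range(n_locations):
        name, mean_c = base[i % 3]
        if i >= 3:
            name = f"{name}{i // 3 + 1}"
        out.append(
            LocationParams(
                location_id=name,
                start_date=dt.date(year, 4, 1),
                mean_c=mean_c,
            )
        )
    return out


def simulate_temperature(params: LocationParams, seed: int) -> TemperatureSeries:
    """Daily mean temperatures: seasonal sinusoid plus Gaussian noise."""
    if params.n_days < 1:
        raise ValueError("season length must be >= 1 day")
    # independent substream per location so multi-location sets differ
    loc_key = zlib.crc32(params.location_id.encode()) % (2**31)
    rng = np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_TEMP_STREAM, loc_key))
    )
    dates = [params.start_date + dt.timedelta(days=i) for i in range(params.n_days)]
    doy = np.array([d.timetuple().tm_yday for d in dates], dtype=float)
    seasonal = params.mean_c + params.amplitude_c * np.cos(
        2.0 * np.pi * (doy - params.peak_doy) / 365.0
    )
    noise = rng.normal(0.0, params.noise_sd_c, size=params.n_days)
    return TemperatureSeries(params.location_id, dates, seasonal + noise)


def simulate_temperatures(
    config: SimConfig, location_params: Optional[list[LocationParams]] = None
) -> dict[str, TemperatureSeries]:
    params = location_params or default_locations(config.n_locations)
    if len(params) != config.n_locations:
        raise ValueError("location parameter count does not match n_locations")
    return {p.location_id: simulate_temperature(p, config.seed) for p in params}


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    truth: TruthRecord,
    config: SimConfig,
    temps: dict[str, TemperatureSeries],
) -> tuple[list[PlotPhenologyRecord], pd.DataFrame]:
    """Plot-level phenology records and the accession x location trait table.

    Per trait and location the genetic value is the sum of planted-QTL
    effects (on the 2 x true-frequency dosage) and a polygenic term with
    covariance proportional to the true-frequency kinship; polygenic values
    are correlated across locations at ``env_genetic_correlation`` while
    shared planted QTLs act identically everywhere. Plot noise is sized so
    the accession x location means reach the target narrow-sense
    heritability. Flowering values (degree-days) are inverted through the
    location's thermal-time accumulation into calendar dates; the sex
    liability is cut at +/- 1 SD into plot scores {1, 2, 3}. The returned
    trait table is the phenology module's aggregation of the records.
    """
    rng = _stream(config.seed, _PHENO_STREAM)
    locations = list(temps.keys())
    n_loc = len(locations)
    if n_loc != config.n_locations:
        raise ValueError("temperature series count does not match n_locations")
    n_acc = len(truth.accessions)
    col = {m: j for j, m in enumerate(truth.marker_ids)}

    # kinship of the noise-free pooled frequencies drives the polygenic term
    K = compute_kinship(
        GenotypeMatrix(
            truth.accessions,
            pd.DataFrame(
                {
                    "marker_id": truth.marker_ids,
                    "scaffold": [m.rsplit("_", 1)[0] for m in truth.marker_ids],
                    "position": [int(m.rsplit("_", 1)[1]) for m in truth.marker_ids],
                    "major": "A",
                    "minor": "C",
                }
            ),
            truth.true_freqs,
        )
    ).values
    L = np.linalg.cholesky(K + 1e-6 * np.eye(n_acc))

    # substream order (fixed): QTL effect signs, then per simulated trait:
    # common polygenic draw, per-location polygenic draws, plot noise
    signs = {id(q): (1.0 if rng.uniform() < 0.5 else -1.0) for q in truth.qtls}

    sim_traits = ("FL_Begin", "FL_Full_gap", "Sex_det")
    h2_of = {
        "FL_Begin": config.h2("FL_Begin"),
        "FL_Full_gap": config.h2("FL_Full"),
        "Sex_det": config.h2("Sex_det"),
    }
    # planted "VEG" QTLs act on FL_Begin (VEG is the calendar-day image of
    # the begin-flowering degree-day value); "FL_Full" QTLs act on the gap
    trait_map = {"FL_Begin": "FL_Begin", "VEG": "FL_Begin",
                 "FL_Full": "FL_Full_gap", "Sex_det": "Sex_det"}

    unit_g: dict[tuple[str, str], np.ndarray] = {}
    plot_z: dict[tuple[str, str], np.ndarray] = {}
    private_counter = 0
    qtls_by_sim: dict[str, list[ResolvedQTL]] = {t: [] for t in sim_traits}
    for q in truth.qtls:
        qtls_by_sim[trait_map[q.trait]].append(q)
        if not q.shared_across_locations:
            q.effects["__private_location__"] = float(private_counter % n_loc)  # type: ignore[assignment]
            private_counter += 1

    for st in sim_traits:
        h2 = h2_of[st]
        z0 = rng.normal(size=n_acc)
        z_loc = rng.normal(size=(n_loc, n_acc))
        rho = config.env_genetic_correlation
        for li, loc in enumerate(locations):
            qtl_term = np.zeros(n_acc)
            vf_sum = 0.0
            for q in qtls_by_sim[st]:
                if not q.shared_across_locations:
                    if int(q.effects["__private_location__"]) != li:
                        continue
                x = _standardize(2.0 * truth.true_freqs[:, col[q.marker_id]])
                a = signs[id(q)] * np.sqrt(q.variance_fraction)
                qtl_term += a * x
                vf_sum += q.variance_fraction
                x_raw = 2.0 * truth.true_freqs[:, col[q.marker_id]]
                sd_raw = x_raw.std()
                q.effects[loc] = float(a / sd_raw) if sd_raw > 0 else 0.0
            sigma_poly2 = max(h2 - vf_sum, 0.0)
            poly = L @ (np.sqrt(rho) * z0 + np.sqrt(1.0 - rho) * z_loc[li])
            poly = _standardize(poly) * np.sqrt(sigma_poly2)
            G = qtl_term + poly
            unit_g[(st, loc)] = G
            truth.variance_decomposition[(st_name(st), loc)] = {
                "qtl": vf_sum,
                "polygenic": sigma_poly2,
                "noise_accession_mean": 1.0 - h2,
            }
        noise_sd = np.sqrt(config.n_plots * (1.0 - h2))
        for li, loc in enumerate(locations):
            e = rng.normal(0.0, 1.0, size=(n_acc, config.n_plots)) * noise_sd
            plot_z[(st, loc)] = unit_g[(st, loc)][:, None] + e

    for q in truth.qtls:
        q.effects.pop("__private_location__", None)

    mean_flb, sd_flb = config.trait_scales["FL_Begin"]
    mean_gap, sd_gap = config.trait_scales["FL_Full_gap"]
    _, sd_sex = config.trait_scales["Sex_det"]

    # genetic values on the reported trait scales
    for loc in locations:
        truth.genetic_values[("FL_Begin", loc)] = sd_flb * unit_g[("FL_Begin", loc)]
        truth.genetic_values[("FL_Full", loc)] = (
            sd_flb * unit_g[("FL_Begin", loc)] + sd_gap * unit_g[("FL_Full_gap", loc)]
        )
        truth.genetic_values[("Sex_det", loc)] = sd_sex * unit_g[("Sex_det", loc)]

    records: list[PlotPhenologyRecord] = []
    for loc in locations:
        series = temps[loc]
        sowing = series.dates[0] + dt.timedelta(days=5)
        emergence = sowing + dt.timedelta(days=7)
        e_idx = series.index_of(emergence)
        daily = np.maximum(series.tmean[e_idx:] - phenology.BASE_TEMP_C, 0.0)
        cum = np.concatenate([[0.0], np.cumsum(daily)])  # cum[k] = deg-days in k days
        h2_sex = h2_of["Sex_det"]
        liability_sd = sd_sex * np.sqrt(
            h2_sex + config.n_plots * (1.0 - h2_sex)
        ) if sd_sex > 0 else 0.0
        for i, acc in enumerate(truth.accessions):
            for p in range(config.n_plots):
                flb_cd = max(mean_flb + sd_flb * plot_z[("FL_Begin", loc)][i, p], 0.0)
                gap_cd = max(
                    mean_gap + sd_gap * plot_z[("FL_Full_gap", loc)][i, p],
                    MIN_FULL_GAP_CD,
                )
                flf_cd = flb_cd + gap_cd
                if flf_cd > cum[-1]:
                    raise ValueError(
                        f"flowering target {flf_cd:.0f} degree-days exceeds the "
                        f"{cum[-1]:.0f} accumulable at {loc}"
                    )
                k_begin = int(np.searchsorted(cum, flb_cd))
                k_full = int(np.searchsorted(cum, flf_cd))
                liab = sd_sex * plot_z[("Sex_det", loc)][i, p]
                if liability_sd == 0:
                    score = 2
                elif liab < -liability_sd:
                    score = 1
                elif liab > liability_sd:
                    score = 3
                else:
                    score = 2
                records.append(
                    PlotPhenologyRecord(
                        location_id=loc,
                        accession_id=acc,
                        plot_id=f"{loc}_p{p + 1}",
                        sowing_date=sowing,
                        emergence_date=emergence,
                        begin_flowering_date=emergence + dt.timedelta(days=k_begin),
                        full_flowering_date=emergence + dt.timedelta(days=k_full),
                        sex_score=score,
                    )
                )

    table = phenology.aggregate_plots(records, temps)
    return records, table


def st_name(sim_trait: str) -> str:
    """Reported trait name behind a simulated component."""
    return {"FL_Begin": "FL_Begin", "FL_Full_gap": "FL_Full", "Sex_det": "Sex_det"}[
        sim_trait
    ]


def simulate_study(
    config: SimConfig,
    location_params: Optional[list[LocationParams]] = None,
) -> tuple[
    GenotypeMatrix,
    TruthRecord,
    dict[str, TemperatureSeries],
    list[PlotPhenologyRecord],
    pd.DataFrame,
]:
    """End-to-end convenience wrapper: panel, temperatures, phenotypes."""
    g, truth = simulate_panel(config)
    temps = simulate_temperatures(config, location_params)
    records, table = simulate_phenotypes(g, truth, config, temps)
    return g, truth, temps, records, table
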