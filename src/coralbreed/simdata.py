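"""Synthetic breeding experiments for a two-population coral cross design.

Emulates the statistical structure of a selective-breeding heat-tolerance
experiment: two diverged source populations (a hot-adapted "PG" population and
a cooler "IO" population), a dam x sire cross design with one-direction
regional hybrids, genotype-dependent larval mortality under heat, and pooled
sequencing read counts with sequencing error.  Every dataset carries a
:class:`SimTruth` record so downstream estimators can be tested for parameter
recovery.

The mortality model is a per-larva Bernoulli survival with

    logit p = baseline(T) + scale(T) * beta * (beneficial copies at causal loci)
              + dam effect + family effect

where ``scale(T)`` is 0 at ambient temperature (genetic heat effects act only
under heat) and ``beta`` is the per-allele-copy log-odds increment.  Loci are
unlinked and segregate independently; linkage is not modelled because the
downstream association and selection scans treat SNPs marginally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

NUCLEOTIDES = np.array(["A", "C", "G", "T"])

#: per-temperature scaling of the causal genetic effect; ambient carries none,
#: the intermediate treatment half of the full heat effect.
DEFAULT_EFFECT_SCALE: Mapping[float, float] = {27.0: 0.0, 33.0: 0.5, 36.0: 1.0}

#: target mean survival per temperature used to calibrate baselines.
DEFAULT_TARGET_SURVIVAL: Mapping[float, float] = {27.0: 0.93, 33.0: 0.75, 36.0: 0.55}


class ParameterError(ValueError):
    """Invalid model or simulation parameter."""


class DesignError(ValueError):
    """Requested cross design is not realisable."""


@dataclass(frozen=True)
class PopulationModel:
    """Two diverged populations with a set of heat-beneficial causal loci.

    Parameters
    ----------
    n_loci
        Total number of biallelic loci.
    divergence
        Balding-Nichols F(ST)-like dispersion in (0, 1); 0 means the two
        populations share identical frequencies at neutral loci.
    causal_loci
        Indices of loci whose beneficial allele increases heat survival.
    causal_effect
        Per-allele-copy log-odds increment to survival under full heat.
    beneficial_freq_hot, beneficial_freq_cool
        Frequency of the beneficial allele in the hot / cool population at
        non-fixed causal loci; the hot frequency must not be below the cool
        one (beneficial alleles are more prevalent where heat selected them).
    fixation_fraction
        Fraction of causal loci at which the beneficial allele is fixed
        (frequency 1.0) in the hot population.
    """

    n_loci: int
    divergence: float = 0.1
    causal_loci: tuple[int, ...] = ()
    causal_effect: float = 0.0
    beneficial_freq_hot: float = 0.75
    beneficial_freq_cool: float = 0.35
    fixation_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ParameterError("n_loci must be >= 1")
        if not 0.0 <= self.divergence < 1.0:
            raise ParameterError("divergence must be in [0, 1)")
        for name in ("beneficial_freq_hot", "beneficial_freq_cool", "fixation_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1]")
        if self.beneficial_freq_hot < self.beneficial_freq_cool:
            raise ParameterError("beneficial_freq_hot must be >= beneficial_freq_cool")
        causal = tuple(self.causal_loci)
        if causal and (min(causal) < 0 or max(causal) >= self.n_loci):
            raise ParameterError("causal_loci must lie in [0, n_loci)")
        if len(set(causal)) != len(causal):
            raise ParameterError("causal_loci must be unique")
        object.__setattr__(self, "causal_loci", causal)


@dataclass(frozen=True)
class CrossDesign:
    """Realised dam x sire crosses with origin categories.

    Hybrids occur in one direction only (cool-origin dam x hot-origin sire);
    ``origin`` is ``PG`` iff both parents are hot-origin and ``IO`` iff both
    are cool-origin.
    """

    dams: tuple[tuple[str, str], ...]   # (id, origin in {"PG","IO"})
    sires: tuple[tuple[str, str], ...]
    crosses: tuple[tuple[str, str, str], ...]  # (dam_id, sire_id, category)

    def __post_init__(self) -> None:
        dam_origin = dict(self.dams)
        sire_origin = dict(self.sires)
        seen = set()
        for dam, sire, cat in self.crosses:
            if (dam, sire) in seen:
                raise DesignError(f"duplicate cross {dam} x {sire}")
            seen.add((dam, sire))
            do, so = dam_origin[dam], sire_origin[sire]
            expected = "PG" if (do, so) == ("PG", "PG") else (
                "IO" if (do, so) == ("IO", "IO") else "PGxIO")
            if (do, so) == ("PG", "IO"):
                raise DesignError("hybrids must be cool-origin dam x hot-origin sire")
            if cat != expected:
                raise DesignError(f"cross {dam} x {sire} mislabelled {cat}")

    @property
    def n_families(self) -> int:
        return len(self.crosses)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"family_id": f"{d}x{s}", "dam_id": d, "sire_id": s, "origin": c}
            for d, s, c in self.crosses
        ]
        return pd.DataFrame(rows)


@dataclass
class SimTruth:
    """Ground truth emitted alongside every simulated dataset."""

    seed: int
    model: PopulationModel
    freq_hot: np.ndarray
    freq_cool: np.ndarray
    parental_genotypes: pd.DataFrame        # parents x loci, copies in {0,1,2}
    family_survival_prob: pd.DataFrame | None = None  # family x temperature
    pool_allele_freq: dict = field(default_factory=dict)  # (family,T) -> freq vector


def simulate_populations(model: PopulationModel, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-locus beneficial/alternate-allele frequencies for both populations.

    Neutral loci follow a Balding-Nichols model: a shared ancestral frequency
    with symmetric divergence noise of strength ``model.divergence`` in each
    population.  Causal loci are set from the model fields, with
    ``fixation_fraction`` of them fixed (frequency 1.0) in the hot population.
    """
    rng = np.random.default_rng(seed)
    ancestral = rng.uniform(0.1, 0.9, size=model.n_loci)
    if model.divergence == 0.0:
        hot = ancestral.copy()
        cool = ancestral.copy()
    else:
        f = model.divergence
        a = ancestral * (1.0 - f) / f
        b = (1.0 - ancestral) * (1.0 - f) / f
        hot = rng.beta(a, b)
        cool = rng.beta(a, b)
    causal = np.asarray(model.causal_loci, dtype=int)
    if causal.size:
        hot[causal] = model.beneficial_freq_hot
        cool[causal] = model.beneficial_freq_cool
        n_fixed = int(round(model.fixation_fraction * causal.size))
        hot[causal[:n_fixed]] = 1.0
    return hot, cool


def draw_parents(
    frequencies: np.ndarray, n_parents: int, seed: int | np.random.Generator,
    ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Draw diploid parental genotypes under Hardy-Weinberg proportions.

    Returns a parents x loci DataFrame of beneficial/alternate allele copy
    counts in {0, 1, 2}.
    """
    freq = np.asarray(frequencies, dtype=float)
    if np.any((freq < 0) | (freq > 1)):
        raise ParameterError("allele frequencies must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    geno = rng.binomial(2, freq, size=(n_parents, freq.size)).astype(np.int8)
    if ids is None:
        ids = [f"P{i}" for i in range(n_parents)]
    return pd.DataFrame(geno, index=list(ids), columns=np.arange(freq.size))


def make_cross_design(
    n_hot_sires: int = 10,
    n_cool_sires: int = 7,
    n_hot_dams: int = 2,
    n_cool_dams: int = 2,
    realized_crosses_per_category: tuple[int, int, int] = (18, 12, 20),
) -> CrossDesign:
    """Enumerate a realised cross design (PG, IO, hybrid counts).

    Enumeration is dam-major then sire, and deterministic: when fewer crosses
    are realised than the combinatorial maximum, the last-enumerated pairs are
    dropped.  Hybrids are always cool-origin dam x hot-origin sire.
    """
    n_pg, n_io, n_hyb = realized_crosses_per_category
    hot_sires = [(f"PG-S{i + 1}", "PG") for i in range(n_hot_sires)]
    cool_sires = [(f"IO-S{i + 1}", "IO") for i in range(n_cool_sires)]
    hot_dams = [(f"PG-D{i + 1}", "PG") for i in range(n_hot_dams)]
    cool_dams = [(f"IO-D{i + 1}", "IO") for i in range(n_cool_dams)]

    maxima = {
        "PG": n_hot_dams * n_hot_sires,
        "IO": n_cool_dams * n_cool_sires,
        "PGxIO": n_cool_dams * n_hot_sires,
    }
    for cat, realized in zip(("PG", "IO", "PGxIO"), (n_pg, n_io, n_hyb)):
        if realized > maxima[cat]:
            raise DesignError(
                f"{cat}: requested {realized} crosses exceeds maximum {maxima[cat]}")

    def enumerate_cat(dams, sires, cat, realized):
        pairs = [(d[0], s[0], cat) for d in dams for s in sires]
        return pairs[:realized]

    crosses = (
        enumerate_cat(hot_dams, hot_sires, "PG", n_pg)
        + enumerate_cat(cool_dams, cool_sires, "IO", n_io)
        + enumerate_cat(cool_dams, hot_sires, "PGxIO", n_hyb)
    )
    return CrossDesign(
        dams=tuple(hot_dams + cool_dams),
        sires=tuple(hot_sires + cool_sires),
        crosses=tuple(crosses),
    )


def make_diagonal_design(n_pg: int, n_io: int, n_hyb: int) -> CrossDesign:
    """Cross design in which every parent is used in exactly one family.

    Unlike the realised experimental design (few dams, shared sires), each
    family here has its own dam and sire, so families are genetically
    independent — the appropriate layout for planted-signal power studies
    where pseudo-replication through shared parents must be excluded.
    """
    dams, sires, crosses = [], [], []
    for i in range(n_pg):
        d, s = (f"PG-D{i + 1}", "PG"), (f"PG-S{i + 1}", "PG")
        dams.append(d); sires.append(s)
        crosses.append((d[0], s[0], "PG"))
    for i in range(n_io):
        d, s = (f"IO-D{i + 1}", "IO"), (f"IO-S{i + 1}", "IO")
        dams.append(d); sires.append(s)
        crosses.append((d[0], s[0], "IO"))
    for i in range(n_hyb):
        d = (f"IO-HD{i + 1}", "IO")
        s = (f"PG-HS{i + 1}", "PG")
        dams.append(d); sires.append(s)
        crosses.append((d[0], s[0], "PGxIO"))
    return CrossDesign(dams=tuple(dams), sires=tuple(sires),
                       crosses=tuple(crosses))


def draw_design_parents(
    design: CrossDesign, model: PopulationModel, seed: int,
) -> tuple[pd.DataFrame, SimTruth]:
    """Draw true genotypes for every dam and sire in a design.

    Hot-origin parents are drawn from the hot population's frequencies and
    cool-origin parents from the cool population's.
    """
    hot, cool = simulate_populations(model, seed)
    rng = np.random.default_rng((seed, 1))
    parents = list(design.dams) + list(design.sires)
    rows = []
    for pid, origin in parents:
        freq = hot if origin == "PG" else cool
        rows.append(rng.binomial(2, freq).astype(np.int8))
    geno = pd.DataFrame(
        np.vstack(rows), index=[p[0] for p in parents],
        columns=np.arange(model.n_loci))
    truth = SimTruth(seed=seed, model=model, freq_hot=hot, freq_cool=cool,
                     parental_genotypes=geno)
    return geno, truth


def calibrate_baselines(
    model: PopulationModel,
    design: CrossDesign,
    parental_genotypes: pd.DataFrame,
    target_survival: Mapping[float, float] = DEFAULT_TARGET_SURVIVAL,
    effect_scale: Mapping[float, float] = DEFAULT_EFFECT_SCALE,
) -> dict[float, float]:
    """Choose per-temperature baseline logits hitting target mean survival.

    The genetic term is not centred in the survival model, so the baseline at
    each heated temperature absorbs the design-mean causal score: baseline(T)
    = logit(target) - scale(T) * beta * mean(causal copies over families).
    """
    causal = np.asarray(model.causal_loci, dtype=int)
    mean_copies = 0.0
    if causal.size:
        per_family = []
        for dam, sire, _ in design.crosses:
            g = (parental_genotypes.loc[dam, causal].to_numpy()
                 + parental_genotypes.loc[sire, causal].to_numpy()) / 2.0
            per_family.append(g.sum())
        mean_copies = float(np.mean(per_family))
    out = {}
    for temp, target in target_survival.items():
        scale = effect_scale.get(float(temp), 1.0)
        out[float(temp)] = float(
            np.log(target / (1.0 - target)) - scale * model.causal_effect * mean_copies)
    return out


def simulate_family_survival(
    design: CrossDesign,
    parental_genotypes: pd.DataFrame,
    model: PopulationModel,
    n_larvae_per_family: int = 270,
    temperatures: Sequence[float] = (27.0, 33.0, 36.0),
    dam_effect_sd: float = 0.3,
    family_effect_sd: float = 0.3,
    seed: int = 0,
    baselines: Mapping[float, float] | None = None,
    effect_scale: Mapping[float, float] = DEFAULT_EFFECT_SCALE,
    n_plates_per_temperature: int = 3,
    truth: SimTruth | None = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate per-larva Mendelian segregation and heat survival.

    Larvae are split evenly across temperatures and plates.  Each larva's
    genotype at every locus is drawn by independent segregation from its
    parents; survival at 60 h is Bernoulli on the logit scale (see module
    docstring).  Returns a plate-level survival table (family x temperature x
    plate alive/dead counts) and the ground-truth record, which also stores
    per-family-x-temperature surviving-pool allele frequencies for the read
    count emitter.
    """
    if n_larvae_per_family < 1:
        raise ParameterError("n_larvae_per_family must be >= 1")
    temps = [float(t) for t in temperatures]
    for t in temps:
        if t not in effect_scale:
            raise ParameterError(f"temperature {t} not in effect_scale map")
    if baselines is None:
        baselines = calibrate_baselines(
            model, design, parental_genotypes,
            {t: DEFAULT_TARGET_SURVIVAL.get(t, 0.5) for t in temps}, effect_scale)

    rng = np.random.default_rng((seed, 2))
    causal = np.asarray(model.causal_loci, dtype=int)
    n_loci = parental_genotypes.shape[1]
    n_per_temp = n_larvae_per_family // len(temps)
    per_plate = max(1, n_per_temp // n_plates_per_temperature)

    if truth is None:
        hot, cool = simulate_populations(model, seed)
        truth = SimTruth(seed=seed, model=model, freq_hot=hot, freq_cool=cool,
                         parental_genotypes=parental_genotypes)

    dam_ids = sorted({d for d, _, _ in design.crosses})
    dam_eff = dict(zip(dam_ids, rng.normal(0.0, dam_effect_sd, len(dam_ids))))

    rows = []
    surv_prob = {}
    pool_freq = {}
    for dam, sire, cat in design.crosses:
        fam = f"{dam}x{sire}"
        fam_eff = rng.normal(0.0, family_effect_sd)
        gd = parental_genotypes.loc[dam].to_numpy()
        gs = parental_genotypes.loc[sire].to_numpy()
        # Mendelian segregation: each gamete carries the beneficial allele
        # with probability parent_copies / 2, independently per locus.
        for temp in temps:
            n = per_plate * n_plates_per_temperature
            gam_d = rng.random((n, n_loci)) < (gd / 2.0)
            gam_s = rng.random((n, n_loci)) < (gs / 2.0)
            larvae = gam_d.astype(np.int8) + gam_s.astype(np.int8)
            score = larvae[:, causal].sum(axis=1) if causal.size else np.zeros(n)
            logit = (baselines[temp]
                     + effect_scale[temp] * model.causal_effect * score
                     + dam_eff[dam] + fam_eff)
            p = 1.0 / (1.0 + np.exp(-logit))
            alive = rng.random(n) < p
            surv_prob[(fam, temp)] = float(p.mean())
            if alive.any():
                pool_freq[(fam, temp)] = larvae[alive].mean(axis=0) / 2.0
            for plate in range(n_plates_per_temperature):
                sl = slice(plate * per_plate, (plate + 1) * per_plate)
                rows.append({
                    "family_id": fam, "dam_id": dam, "sire_id": sire,
                    "origin": cat, "temperature": temp, "plate": plate + 1,
                    "n_start": per_plate, "n_alive_60h": int(alive[sl].sum()),
                })
    table = pd.DataFrame(rows)
    truth.family_survival_prob = (
        pd.Series(surv_prob).rename_axis(["family_id", "temperature"])
        .rename("survival_prob").reset_index())
    truth.pool_allele_freq = pool_freq
    return table, truth


def assign_locus_alleles(n_loci: int, seed: int) -> pd.DataFrame:
    """Assign a reference (ancestral) and alternate base to each locus.

    The simulator's reference base is the ancestral allele; the "beneficial /
    alternate" frequency axis used throughout the truth record counts the
    alternate base.
    """
    rng = np.random.default_rng((seed, 3))
    ref_idx = rng.integers(0, 4, n_loci)
    alt_off = rng.integers(1, 4, n_loci)
    alt_idx = (ref_idx + alt_off) % 4
    return pd.DataFrame({
        "locus_id": [f"L{i:05d}" for i in range(n_loci)],
        "contig": [f"contig_{i // 100}" for i in range(n_loci)],
        "position": [(i % 100) * 40 for i in range(n_loci)],
        "ref_base": NUCLEOTIDES[ref_idx],
        "alt_base": NUCLEOTIDES[alt_idx],
    })


def _counts_with_error(
    rng: np.random.Generator,
    depth: np.ndarray,
    alt_frac: np.ndarray,
    ref_idx: np.ndarray,
    alt_idx: np.ndarray,
    error_rate: float,
) -> np.ndarray:
    """Per-locus A/C/G/T counts from true alt fraction with uniform base error."""
    n = depth.size
    alt_true = rng.binomial(depth, np.clip(alt_frac, 0.0, 1.0))
    ref_true = depth - alt_true
    counts = np.zeros((n, 4), dtype=np.int64)
    for true_idx, n_true in ((ref_idx, ref_true), (alt_idx, alt_true)):
        if error_rate > 0.0:
            n_err = rng.binomial(n_true, error_rate)
            kept = n_true - n_err
            # each erroneous read lands uniformly on one of the 3 other bases
            err_split = rng.multinomial(n_err, [1 / 3] * 3)
        else:
            kept = n_true
            err_split = np.zeros((n, 3), dtype=np.int64)
        np.add.at(counts, (np.arange(n), true_idx), kept)
        others = np.array([[b for b in range(4) if b != t] for t in true_idx])
        for j in range(3):
            np.add.at(counts, (np.arange(n), others[:, j]), err_split[:, j])
    return counts


def emit_read_counts(
    sample_fracs: Mapping[str, np.ndarray],
    registry: pd.DataFrame,
    mean_depth: float,
    error_rate: float,
    seed: int,
    depth_dispersion: float | None = None,
) -> pd.DataFrame:
    """Emit per-locus nucleotide read-count tables for a set of samples.

    ``sample_fracs`` maps sample id to the true alternate-allele fraction per
    locus (a parent: 0, 0.5 or 1; a pool: the frequency among survivors).
    Depth is Poisson with the given mean by default, or negative binomial when
    ``depth_dispersion`` (> 0, smaller = more overdispersed) is supplied.
    Each read is miscalled to a uniformly random other base with probability
    ``error_rate``.
    """
    if mean_depth <= 0:
        raise ParameterError("mean_depth must be > 0")
    if not 0.0 <= error_rate < 0.5:
        raise ParameterError("error_rate must be in [0, 0.5)")
    rng = np.random.default_rng((seed, 4))
    base_to_idx = {b: i for i, b in enumerate(NUCLEOTIDES)}
    ref_idx = registry["ref_base"].map(base_to_idx).to_numpy()
    alt_idx = registry["alt_base"].map(base_to_idx).to_numpy()
    n_loci = len(registry)
    frames = []
    for sample_id, frac in sample_fracs.items():
        frac = np.asarray(frac, dtype=float)
        if frac.size != n_loci:
            raise ParameterError(
                f"sample {sample_id}: {frac.size} fractions for {n_loci} loci")
        if depth_dispersion is None:
            depth = rng.poisson(mean_depth, n_loci)
        else:
            k = depth_dispersion
            depth = rng.negative_binomial(k, k / (k + mean_depth), n_loci)
        counts = _counts_with_error(rng, depth, frac, ref_idx, alt_idx, error_rate)
        frames.append(pd.DataFrame({
            "locus_id": registry["locus_id"].to_numpy(),
            "sample_id": sample_id,
            "A": counts[:, 0], "C": counts[:, 1],
            "G": counts[:, 2], "T": counts[:, 3],
        }))
    return pd.concat(frames, ignore_index=True)


def make_field_table() -> pd.DataFrame:
    """Synthetic reconstruction of the juvenile field-deployment outcome.

    20 families (8 hybrid, 6 Indian Ocean, 6 Persian Gulf) deployed to the
    cooler reef; per-origin deployed totals (1031/237/1068) with survivor
    counts (20/5/3) chosen as the integers nearest the reported per-origin
    survival rates (1.92%, 1.93%, 0.31%) and survivor-family fractions
    (63%, 50%, 33%).  This is a reconstruction from printed summary values,
    not measured data.
    """
    rows = []

    def origin_block(origin, n_fam, deployed_total, survivors, fam_with):
        per, extra = divmod(deployed_total, n_fam)
        surv_split = [0] * n_fam
        for i in range(survivors):
            surv_split[i % fam_with] += 1
        for i in range(n_fam):
            rows.append({
                "family_id": f"{origin}-F{i + 1}", "origin": origin,
                "n_deployed": per + (1 if i < extra else 0),
                "n_survivors": surv_split[i],
            })

    origin_block("PGxIO", 8, 1031, 20, 5)
    origin_block("IO", 6, 237, 5, 3)
    origin_block("PG", 6, 1068, 3, 2)
    return pd.DataFrame(rows)


def make_annotation(
    registry: pd.DataFrame,
    seed: int,
    frac_intragenic: float = 0.8,
    loci_per_gene: int = 5,
    n_terms: int = 120,
    max_terms_per_gene: int = 6,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic locus -> gene and gene -> GO-term annotation maps.

    Consecutive intragenic loci share a gene (RAD tags cluster within genes);
    the remainder are intergenic (empty gene_id).  Each gene draws 1 to
    ``max_terms_per_gene`` terms from a fixed synthetic vocabulary.  Returns
    (registry with a gene_id column, gene_id/terms frame).
    """
    rng = np.random.default_rng((seed, 5))
    n = len(registry)
    reg = registry.copy()
    gene_ids = np.array([f"gene_{i // loci_per_gene:04d}" for i in range(n)],
                        dtype=object)
    intergenic = rng.random(n) >= frac_intragenic
    gene_ids[intergenic] = ""
    reg["gene_id"] = gene_ids
    vocab = [f"GO:{i:07d}" for i in range(1, n_terms + 1)]
    genes = sorted({g for g in gene_ids if g})
    rows = []
    for g in genes:
        k = rng.integers(1, max_terms_per_gene + 1)
        terms = sorted(rng.choice(vocab, size=k, replace=False))
        rows.append({"gene_id": g, "terms": ",".join(terms)})
    return reg, pd.DataFrame(rows)


def pool_sample_id(family_id: str, temperature: float) -> str:
    return f"{family_id}@{temperature:g}C"


def parse_pool_sample_id(sample_id: str) -> tuple[str, float]:
    fam, temp = sample_id.rsplit("@", 1)
    return fam, float(temp.rstrip("C"))
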