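"""Synthetic cfDNA cohorts with nucleosome-depleted promoters.

Emulates the study conditions the pipeline is built for: low-coverage
(~0.3×) single-end WGS of plasma cfDNA, mono-nucleosome fragment sizes,
promoter coverage depleted in proportion to gene activity, two patient
classes (ALN-positive / ALN-negative) differing in promoter coverage at a
controllable fraction of genes, clinical covariates matching the cohort's
overall marginal frequencies, and a per-sample tumor fraction.

Two paths are provided: a full fragment-level simulator (reads → BAM/BED →
coverage) and a fast path that draws the normalized promoter-profile
matrix directly, for classifier-scale experiments.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .fragments import FragmentSet
from .profiling import PromoterProfileMatrix

POSITIVE = "ALN-positive"
NEGATIVE = "ALN-negative"

#: overall covariate frequencies of the 330-patient cohort design
DEFAULT_COVARIATE_MARGINALS = {
    "ER": 272 / 330,
    "PR": 272 / 330,
    "Her2": 274 / 330,
    "Ki67_high": 184 / 330,
    "t_stage": (140 / 330, 154 / 330, 36 / 330),  # T1, T2, T3/4
    "grade": (25 / 330, 237 / 330, 68 / 330),  # 1, 2, 3
    "age_mean": 51.4,
    "age_sd": 10.0,
}


class SimulationError(ValueError):
    pass


@dataclass
class NucleosomeModel:
    """Fragment-generation model around promoters.

    ``ndr_depth`` is the maximal fractional coverage loss at a fully active
    promoter; the depletion is Gaussian-shaped with scale ``ndr_halfwidth``
    centred on the TSS, with a faint phased-nucleosome ripple of period
    ``spacing`` outside the depleted core. ``gc_bias_strength`` > 0 thins
    fragments by a logistic function of GC content so the GC correction has
    something real to remove.
    """

    fragment_length_mean: float = 167.0
    fragment_length_sd: float = 15.0
    ndr_depth: float = 0.5
    ndr_halfwidth: float = 150.0
    spacing: float = 190.0
    gc_bias_strength: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.ndr_depth <= 1.0:
            raise SimulationError("ndr_depth must be in [0, 1]")
        for name in ("fragment_length_mean", "fragment_length_sd", "ndr_halfwidth", "spacing"):
            if getattr(self, name) <= 0:
                raise SimulationError(f"{name} must be positive")


@dataclass
class CohortTruth:
    """Ground truth for a simulated cohort.

    ``genes``: gene_id, activity ∈ [0,1], housekeeping flag, differential
    flag, fold_change (≥ 1; class-mean promoter coverage ratio) and
    direction of the change in ALN-positive samples.
    ``samples``: sample_id, label, binary ER/PR/Her2/Ki67_high, ordinal
    t_stage and grade, age in years, tumor_fraction ∈ [0,1].
    """

    genes: pd.DataFrame = field(repr=False)
    samples: pd.DataFrame = field(repr=False)
    seed: int = 0

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def labels(self) -> pd.Series:
        return self.samples.set_index("sample_id")["label"]

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "genes": self.genes.to_dict(orient="list"),
            "samples": self.samples.to_dict(orient="list"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "CohortTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            genes=pd.DataFrame(payload["genes"]),
            samples=pd.DataFrame(payload["samples"]),
            seed=payload["seed"],
        )


def generate_cohort_truth(
    n_pos: int,
    n_neg: int,
    n_genes: int = 500,
    frac_diff: float = 0.05,
    fc: float = 1.5,
    frac_housekeeping: float = 0.25,
    seed: int = 0,
    covariate_marginals: dict | None = None,
    tumor_fraction_beta: tuple[float, float] = (2.0, 18.0),
) -> CohortTruth:
    """Draw cohort-level ground truth.

    Exactly ``round(frac_diff * n_genes)`` genes are flagged differential
    with fold change ``fc``; the direction (coverage increased or decreased
    in ALN-positive) is randomized per gene. Covariates are drawn from the
    cohort's overall marginal frequencies; tumor fraction from a Beta
    distribution (default mean 0.1, matching low-burden early disease).
    """
    if n_pos < 0 or n_neg < 0:
        raise SimulationError("cohort sizes must be non-negative")
    if not 0.0 <= frac_diff <= 1.0:
        raise SimulationError("frac_diff must be in [0, 1]")
    if fc <= 0:
        raise SimulationError("fold change must be positive")
    rng = np.random.default_rng(seed)
    marg = {**DEFAULT_COVARIATE_MARGINALS, **(covariate_marginals or {})}

    n_diff = int(round(frac_diff * n_genes))
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    housekeeping = np.zeros(n_genes, bool)
    housekeeping[rng.choice(n_genes, size=int(round(frac_housekeeping * n_genes)), replace=False)] = True
    # active (housekeeping-like) promoters carry deep NDRs; the rest are shallow
    activity = np.where(housekeeping, rng.uniform(0.8, 1.0, n_genes), rng.uniform(0.0, 0.4, n_genes))
    differential = np.zeros(n_genes, bool)
    differential[rng.choice(n_genes, size=n_diff, replace=False)] = True
    # differential genes need headroom for class scaling of their depletion
    activity[differential] = rng.uniform(0.4, 0.6, n_diff)
    direction = np.where(differential, rng.choice(["increased", "decreased"], n_genes), "none")
    genes = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "activity": activity,
            "housekeeping": housekeeping,
            "differential": differential,
            "fold_change": np.where(differential, fc, 1.0),
            "direction": direction,
        }
    )

    n = n_pos + n_neg
    labels = np.array([POSITIVE] * n_pos + [NEGATIVE] * n_neg)
    a, b = tumor_fraction_beta
    t_stage = rng.choice([1, 2, 3], size=n, p=np.asarray(marg["t_stage"]) / sum(marg["t_stage"]))
    grade = rng.choice([1, 2, 3], size=n, p=np.asarray(marg["grade"]) / sum(marg["grade"]))
    samples = pd.DataFrame(
        {
            "sample_id": [f"s{i:04d}" for i in range(n)],
            "label": labels,
            "ER": (rng.random(n) < marg["ER"]).astype(int),
            "PR": (rng.random(n) < marg["PR"]).astype(int),
            "Her2": (rng.random(n) < marg["Her2"]).astype(int),
            "Ki67_high": (rng.random(n) < marg["Ki67_high"]).astype(int),
            "t_stage": t_stage,
            "grade": grade,
            "age": np.round(np.clip(rng.normal(marg["age_mean"], marg["age_sd"], n), 25, 90), 1),
            "tumor_fraction": rng.beta(a, b, n),
        }
    )
    return CohortTruth(genes=genes, samples=samples, seed=seed)


# ------------------------------------------------------- fast matrix path


def simulate_profile_matrix(
    truth: CohortTruth,
    noise_cv: float = 0.25,
    base_mean: float = 0.5,
    seed: int = 0,
) -> PromoterProfileMatrix:
    """Draw the gene-level profile matrix directly from the truth table.

    Each gene's class means have ratio exactly equal to its fold change
    (split symmetrically about a base mean that decreases with promoter
    activity, mimicking NDR coverage loss); values are lognormal with
    coefficient of variation ``noise_cv``. ``noise_cv=0`` returns the class
    means exactly.
    """
    if noise_cv < 0:
        raise SimulationError("noise_cv must be non-negative")
    rng = np.random.default_rng(seed)
    g = truth.genes
    base = base_mean * (1.0 - 0.6 * g["activity"].to_numpy())
    fc = g["fold_change"].to_numpy()
    up = g["direction"].to_numpy() == "increased"
    # coverage increased in ALN-positive → mean_pos = base*sqrt(fc)
    mean_pos = np.where(up, base * np.sqrt(fc), base / np.sqrt(fc))
    mean_neg = np.where(up, base / np.sqrt(fc), base * np.sqrt(fc))
    is_pos = (truth.samples["label"] == POSITIVE).to_numpy()
    means = np.where(is_pos[:, None], mean_pos[None, :], mean_neg[None, :])
    if noise_cv == 0:
        vals = means
    else:
        sigma = np.sqrt(np.log1p(noise_cv**2))
        mu = np.log(means) - sigma**2 / 2
        vals = rng.lognormal(mu, sigma)
    df = pd.DataFrame(vals, index=truth.samples["sample_id"].to_numpy(), columns=g["gene_id"])
    df.index.name = "sample_id"
    df.columns.name = None
    return PromoterProfileMatrix(df, level="gene")


# ---------------------------------------------------- fragment-level path


def _gc_at(positions: np.ndarray, rng_field_period: float = 50_000.0) -> np.ndarray:
    # smooth deterministic GC landscape around the genome-wide mean 0.41
    return 0.41 + 0.08 * np.sin(2 * np.pi * positions / rng_field_period)


def sample_genome_gc(chrom_length: int, n: int = 50_000, seed: int = 0) -> np.ndarray:
    """GC fractions at uniformly sampled positions of the synthetic genome.

    Serves as the expected-GC reference for
    :func:`cfpromoter.profiling.gc_correct`.
    """
    rng = np.random.default_rng(seed)
    return _gc_at(rng.integers(0, chrom_length, size=n))


def _depletion_profile(offsets: np.ndarray, depth: np.ndarray, model: NucleosomeModel) -> np.ndarray:
    """Fractional intensity loss at signed distances from a TSS."""
    sig = model.ndr_halfwidth
    core = np.exp(-(offsets**2) / (2 * sig**2))
    ripple = (
        0.15
        * np.cos(2 * np.pi * offsets / model.spacing)
        * np.exp(-np.abs(offsets) / (4 * sig))
        * (1 - core)
    )
    return np.clip(depth * (core - ripple), 0.0, 0.98)


def _class_activity(truth: CohortTruth) -> tuple[np.ndarray, np.ndarray]:
    g = truth.genes
    act = g["activity"].to_numpy()
    fc = g["fold_change"].to_numpy()
    up = g["direction"].to_numpy() == "increased"
    dn = g["direction"].to_numpy() == "decreased"
    # decreased coverage in positives ⇒ deeper depletion in positives
    act_pos = np.where(dn, np.minimum(1.0, act * np.sqrt(fc)), act)
    act_pos = np.where(up, act / np.sqrt(fc), act_pos)
    act_neg = np.where(up, np.minimum(1.0, act * np.sqrt(fc)), act)
    act_neg = np.where(dn, act / np.sqrt(fc), act_neg)
    return act_pos, act_neg


def simulate_fragments(
    truth: CohortTruth,
    annotation: pd.DataFrame,
    model: NucleosomeModel,
    mean_depth: float = 0.3,
    chrom_length: int | None = None,
    seed: int = 0,
) -> list[FragmentSet]:
    """Simulate one FragmentSet per cohort sample.

    Fragment midpoints follow a flat background intensity minus a
    Gaussian-shaped depletion of relative depth ``ndr_depth × activity``
    at each TSS (activity scaled per class at differential genes); lengths
    are truncated-normal; expected base coverage equals ``mean_depth``.
    Deterministic per (seed, sample index).
    """
    if mean_depth <= 0:
        raise SimulationError("mean_depth must be positive")
    if set(annotation["gene_id"]) != set(truth.genes["gene_id"]):
        raise SimulationError("annotation and truth disagree on gene IDs")
    if chrom_length is None:
        chrom_length = int(annotation["tss"].max() + 10_000)
    chrom = annotation["chrom"].iloc[0]
    ann = annotation.set_index("gene_id").loc[truth.genes["gene_id"].to_numpy()]
    act_pos, act_neg = _class_activity(truth)
    # sort TSS ascending and carry the per-gene activities along
    tss_order = np.argsort(ann["tss"].to_numpy(), kind="stable")
    tss = ann["tss"].to_numpy()[tss_order]
    act_pos, act_neg = act_pos[tss_order], act_neg[tss_order]

    n_expected = mean_depth * chrom_length / model.fragment_length_mean
    reach = 6 * model.ndr_halfwidth
    out: list[FragmentSet] = []
    for i, row in enumerate(truth.samples.itertuples(index=False)):
        rng = np.random.default_rng([seed, i])
        act = act_pos if row.label == POSITIVE else act_neg
        depth_g = model.ndr_depth * act
        n_frag = int(round(n_expected))
        mids = np.empty(0, dtype=np.int64)
        while mids.size < n_frag:
            m = int((n_frag - mids.size) * 1.6) + 16
            cand = rng.integers(0, chrom_length, size=m)
            # nearest TSS (sorted) is the only one within reach
            j = np.clip(np.searchsorted(tss, cand), 0, len(tss) - 1)
            j = np.where((j > 0) & (np.abs(cand - tss[j - 1]) < np.abs(cand - tss[j])), j - 1, j)
            off = cand - tss[j]
            dep = np.where(np.abs(off) < reach, _depletion_profile(off, depth_g[j], model), 0.0)
            accept = rng.random(m) >= dep
            if model.gc_bias_strength != 0:
                gc = _gc_at(cand)
                keep_p = 1.0 / (1.0 + np.exp(-model.gc_bias_strength * (gc - 0.41)))
                accept &= rng.random(m) < keep_p
            mids = np.concatenate([mids, cand[accept]])
        mids = mids[:n_frag]
        lengths = np.clip(
            np.round(rng.normal(model.fragment_length_mean, model.fragment_length_sd, n_frag)),
            50,
            2 * model.fragment_length_mean,
        ).astype(np.int64)
        starts = np.clip(mids - lengths // 2, 0, chrom_length - 1)
        ends = np.minimum(starts + lengths, chrom_length)
        order = np.argsort(starts, kind="stable")
        gc = np.clip(_gc_at(mids) + rng.normal(0, 0.02, n_frag), 0.0, 1.0)
        rec = pd.DataFrame(
            {
                "chrom": chrom,
                "start": starts[order],
                "end": ends[order],
                "gc": np.round(gc[order], 4),
            }
        )
        out.append(FragmentSet(row.sample_id, rec))
    return out
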