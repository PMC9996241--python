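"""Synthetic multiomics cohort with planted ground truth.

The generator emulates the statistical structure the downstream analyses
assume: phosphosite log2 fold-changes confounded by host-protein abundance,
additive per-study batch effects on every layer, kinase/TF activity shifts
propagated to substrate sites and target transcripts, mutation carriers with
planted activity effects, and survival times whose hazard depends on planted
regulator activities.  Samples fall into latent blocks of co-active
regulators, which is what the sample-stratification stage is expected to
recover.

Everything is a deterministic function of the `SimConfig` (including its
seed): the same configuration always yields byte-identical outputs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import (
    EdgeList,
    FeatureMatrix,
    GoldStandardPair,
    MutationRecord,
    PhosphositeKey,
    PriorNetwork,
)

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRVW"))  # S/T/Y reserved for sites

_LOF_CLASSES = ("frameshift_indel", "nonsense", "splice_site", "stop_loss")


@dataclass
class SimConfig:
    """Parameters of the simulated cohort.

    Magnitudes default to the regime the pipeline must detect: a one
    log2-unit substrate shift (`activity_shift`) against unit phosphosite
    noise, a 0.8 protein-confounding slope (phosphosite changes largely
    mirror protein abundance, as observed in tumour proteomes), and modest
    per-study batch offsets.
    """

    n_samples: int = 300
    n_studies: int = 3
    n_blocks: int = 3
    n_kinases: int = 50
    n_tfs: int = 40
    n_genes: int = 1000
    substrates_per_kinase: int = 10
    targets_per_tf: int = 20
    n_background_sites: int = 500
    n_self_sites_per_kinase: int = 2  # regulatory-like sites on the kinase
    active_fraction: float = 0.1  # overall fraction of samples a regulator is active in
    activity_shift: float = 1.0  # log2FC units added to substrates/targets
    phospho_noise_sd: float = 1.0
    mrna_noise_sd: float = 1.0
    protein_noise_sd: float = 0.5
    protein_confounding_slope: float = 0.8
    batch_effect_sd: float = 0.3
    lof_protein_effect: float = -0.5  # log2FC drop for LoF carrier proteins
    # None -> plant the default effects/hazards; [] -> plant nothing
    mutation_effects: list[tuple[str, str, float]] | None = None
    mutation_carrier_fraction: float = 0.15
    background_mutation_rate: float = 0.01
    hazards: list[tuple[str, float]] | None = None
    baseline_hazard: float = 1e-3  # events per day
    censor_max_days: float = 3000.0
    n_gold_positives: int = 50
    missingness_rate: float = 0.1
    max_sites_per_protein: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_studies", "n_blocks", "n_kinases", "n_tfs",
                     "n_genes", "substrates_per_kinase", "targets_per_tf"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("missingness_rate", "mutation_carrier_fraction",
                     "background_mutation_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        n_hosts = self.n_genes - self.n_kinases - self.n_tfs
        if n_hosts < 1:
            raise ValueError("n_genes must exceed n_kinases + n_tfs")
        capacity = n_hosts * self.max_sites_per_protein
        if self.n_kinases * self.substrates_per_kinase > capacity:
            raise ValueError(
                f"substrate demand {self.n_kinases * self.substrates_per_kinase} "
                f"exceeds available site space {capacity}")

    def with_defaults_planted(self) -> "SimConfig":
        """Fill empty mutation-effect / hazard lists with default plantings."""
        cfg = self
        if cfg.mutation_effects is None:
            genes = [f"GEN{i:04d}" for i in range(1, 6)]
            kinases = [f"KIN{i:03d}" for i in range(1, 6)]
            cfg = dataclass_replace(cfg, mutation_effects=[
                (g, k, 1.0) for g, k in zip(genes, kinases)])
        if cfg.hazards is None:
            cfg = dataclass_replace(cfg, hazards=[("KIN001", np.log(2.0)),
                                                  ("TF001", np.log(2.0))])
        return cfg


def dataclass_replace(cfg: SimConfig, **kwargs) -> SimConfig:
    import dataclasses

    return dataclasses.replace(cfg, **kwargs)


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generator."""

    true_activity: pd.DataFrame  # regulator x sample, values in {-1, 0, +1}
    true_effects: list[tuple[str, str, float]]
    true_hazards: list[tuple[str, float]]
    cluster_labels: pd.Series  # sample -> block id


@dataclass
class Cohort:
    mrna: FeatureMatrix
    protein: FeatureMatrix
    phospho: FeatureMatrix
    cnv: FeatureMatrix
    mutations: list[MutationRecord]
    clinical: pd.DataFrame
    truth: SyntheticTruth


@dataclass
class Priors:
    network: PriorNetwork
    edges: EdgeList
    gold_standard: list[GoldStandardPair]
    fasta: dict[str, str]


@dataclass
class Simulation:
    cohort: Cohort
    priors: Priors


# ---------------------------------------------------------------------------


def _site_id(site: PhosphositeKey) -> str:
    return str(site)


def simulate(config: SimConfig) -> Simulation:
    """Run the full generator; one deterministic pass builds cohort + priors."""
    cfg = config.with_defaults_planted()
    rng = np.random.default_rng(cfg.seed)

    samples = [f"S{i:04d}" for i in range(1, cfg.n_samples + 1)]
    kinases = [f"KIN{i:03d}" for i in range(1, cfg.n_kinases + 1)]
    tfs = [f"TF{i:03d}" for i in range(1, cfg.n_tfs + 1)]
    n_other = cfg.n_genes - cfg.n_kinases - cfg.n_tfs
    others = [f"GEN{i:04d}" for i in range(1, n_other + 1)]
    genes = kinases + tfs + others
    regulators = kinases + tfs

    studies = pd.Series([f"study{(i % cfg.n_studies) + 1}" for i in range(cfg.n_samples)],
                        index=samples, name="study")
    blocks = pd.Series(rng.integers(1, cfg.n_blocks + 1, size=cfg.n_samples),
                       index=samples, name="block")

    # --- planted regulator activity: sparse, block-structured signed
    # indicators.  Each regulator belongs to one latent block and is active
    # only in samples of that block, thinned so that the overall active
    # fraction matches `active_fraction` (regulation is rare: in tumour
    # cohorts a regulator is strongly regulated in a minority of samples).
    reg_block = rng.integers(1, cfg.n_blocks + 1, size=len(regulators))
    reg_sign = rng.choice([-1, 1], size=len(regulators))
    within_block_rate = min(1.0, cfg.active_fraction * cfg.n_blocks)
    act = np.zeros((len(regulators), cfg.n_samples))
    for i in range(len(regulators)):
        in_block = blocks.to_numpy() == reg_block[i]
        thinned = in_block & (rng.random(cfg.n_samples) < within_block_rate)
        act[i, :] = np.where(thinned, reg_sign[i], 0)
    true_activity = pd.DataFrame(act, index=regulators, columns=samples)

    # --- wiring: substrates on non-regulator host proteins, TF target genes
    site_pool = [(host, pos) for host in others
                 for pos in range(1, cfg.max_sites_per_protein + 1)]
    picked = rng.choice(len(site_pool),
                        size=cfg.n_kinases * cfg.substrates_per_kinase
                        + min(cfg.n_background_sites, len(site_pool)
                              - cfg.n_kinases * cfg.substrates_per_kinase),
                        replace=False)
    residues = rng.choice(np.array(list("STY")), size=len(picked),
                          p=[0.6, 0.25, 0.15])
    sites = [PhosphositeKey(site_pool[j][0], 2 * site_pool[j][1], r)
             for j, r in zip(picked, residues)]  # even positions keep sites apart
    kin_sites = {
        kin: sites[i * cfg.substrates_per_kinase:(i + 1) * cfg.substrates_per_kinase]
        for i, kin in enumerate(kinases)
    }
    background_sites = sites[cfg.n_kinases * cfg.substrates_per_kinase:]
    site_kinase: dict[PhosphositeKey, str] = {
        s: kin for kin, ss in kin_sites.items() for s in ss}
    # Autoregulatory-like sites on the kinase protein itself: carry the
    # kinase's activity signal but are not part of the substrate prior.
    for kin in kinases:
        for j in range(cfg.n_self_sites_per_kinase):
            site = PhosphositeKey(kin, 2 * (j + 1), "S")
            sites.append(site)
            site_kinase[site] = kin

    tf_targets: dict[str, list[tuple[str, int]]] = {}
    target_pool = np.array(others)
    for tf in tfs:
        chosen = rng.choice(target_pool, size=cfg.targets_per_tf, replace=False)
        modes = rng.choice([-1, 1], size=cfg.targets_per_tf, p=[0.25, 0.75])
        tf_targets[tf] = list(zip(chosen.tolist(), modes.tolist()))

    # --- batch offsets per (study, feature) and per layer
    study_names = sorted(studies.unique())
    study_idx = studies.map({s: i for i, s in enumerate(study_names)}).to_numpy()

    def batch(n_features: int) -> np.ndarray:
        offsets = rng.normal(0.0, cfg.batch_effect_sd,
                             size=(n_features, len(study_names)))
        return offsets[:, study_idx]

    # --- mutations (planted carriers + background), before matrices so the
    #     LoF protein effect and activity effects can be applied
    carriers: dict[str, np.ndarray] = {}
    mutation_rows: list[tuple[str, str, str]] = []  # (sample, gene, class)
    for g, _, _ in cfg.mutation_effects:
        mask = rng.random(cfg.n_samples) < cfg.mutation_carrier_fraction
        carriers[g] = mask
        for s in np.array(samples)[mask]:
            mutation_rows.append((s, g, "missense"))
    classes = np.array(["missense", "nonsense", "frameshift_indel",
                        "inframe_indel", "splice_site", "stop_loss", "silent"])
    class_p = np.array([0.5, 0.1, 0.1, 0.05, 0.1, 0.05, 0.1])
    n_bg = rng.binomial(cfg.n_samples * len(genes), cfg.background_mutation_rate)
    bg_samples = rng.choice(samples, size=n_bg)
    bg_genes = rng.choice(genes, size=n_bg)
    bg_classes = rng.choice(classes, size=n_bg, p=class_p)
    planted = {(s, g) for s, g, _ in mutation_rows}
    for s, g, c in zip(bg_samples, bg_genes, bg_classes):
        if (s, g) not in planted:
            mutation_rows.append((s, g, c))

    lof_carrier = np.zeros((len(genes), cfg.n_samples), dtype=bool)
    gene_index = {g: i for i, g in enumerate(genes)}
    sample_index = {s: i for i, s in enumerate(samples)}
    for s, g, c in mutation_rows:
        if c in _LOF_CLASSES:
            lof_carrier[gene_index[g], sample_index[s]] = True

    # --- mutation -> activity effects on the substrate-shift scale
    extra_shift = np.zeros((len(regulators), cfg.n_samples))
    reg_index = {r: i for i, r in enumerate(regulators)}
    for g, target, beta in cfg.mutation_effects:
        extra_shift[reg_index[target], :] += beta * carriers[g].astype(float)
    effective_act = true_activity.to_numpy() * cfg.activity_shift + extra_shift

    # --- layers
    protein_vals = (batch(len(genes))
                    + rng.normal(0.0, cfg.protein_noise_sd,
                                 size=(len(genes), cfg.n_samples)))
    protein_vals = protein_vals + cfg.lof_protein_effect * lof_carrier

    mrna_vals = (batch(len(genes))
                 + rng.normal(0.0, cfg.mrna_noise_sd,
                              size=(len(genes), cfg.n_samples)))
    for tf in tfs:
        tf_act = effective_act[reg_index[tf], :]
        for gene, mode in tf_targets[tf]:
            mrna_vals[gene_index[gene], :] += mode * tf_act

    site_ids = [_site_id(s) for s in sites]
    phospho_vals = (batch(len(sites))
                    + rng.normal(0.0, cfg.phospho_noise_sd,
                                 size=(len(sites), cfg.n_samples)))
    for i, site in enumerate(sites):
        phospho_vals[i, :] += (cfg.protein_confounding_slope
                               * protein_vals[gene_index[site.protein], :])
        kin = site_kinase.get(site)
        if kin is not None:
            phospho_vals[i, :] += effective_act[reg_index[kin], :]

    cnv_vals = rng.choice(np.array([-2.0, -1.0, 0.0, 1.0, 2.0]),
                          size=(len(genes), cfg.n_samples),
                          p=[0.02, 0.08, 0.80, 0.08, 0.02])

    # --- missingness, completely at random (cnv kept complete)
    def punch(values: np.ndarray) -> np.ndarray:
        mask = rng.random(values.shape) < cfg.missingness_rate
        out = values.copy()
        out[mask] = np.nan
        return out

    mrna = FeatureMatrix(pd.DataFrame(punch(mrna_vals), index=genes,
                                      columns=samples), "mrna")
    protein = FeatureMatrix(pd.DataFrame(punch(protein_vals), index=genes,
                                         columns=samples), "protein")
    phospho = FeatureMatrix(pd.DataFrame(punch(phospho_vals), index=site_ids,
                                         columns=samples), "phospho")
    cnv = FeatureMatrix(pd.DataFrame(cnv_vals, index=genes, columns=samples),
                        "cnv")

    # --- sequences satisfying site residues; mutations read ref from sequence
    seq_len = 2 * cfg.max_sites_per_protein + 10
    sequences: dict[str, str] = {}
    for g in genes:
        chars = rng.choice(AMINO_ACIDS, size=seq_len)
        sequences[g] = "".join(chars)
    for site in sites:
        seq = sequences[site.protein]
        sequences[site.protein] = (seq[:site.position - 1] + site.residue
                                   + seq[site.position:])

    mutation_records: list[MutationRecord] = []
    for s, g, c in mutation_rows:
        if c == "splice_site":
            mutation_records.append(MutationRecord(s, g, c))
            continue
        pos = int(rng.integers(1, seq_len + 1))
        ref = sequences[g][pos - 1]
        alt = str(rng.choice(AMINO_ACIDS[AMINO_ACIDS != ref]))
        mutation_records.append(MutationRecord(s, g, c, pos, ref, alt))
    mutation_records.sort(key=lambda r: (r.sample_id, r.gene, r.mclass,
                                         r.position or 0))

    # --- clinical table with exponential survival, uniform censoring
    age = np.round(rng.normal(60.0, 10.0, size=cfg.n_samples)).clip(20, 95)
    gender = rng.choice(np.array(["female", "male"]), size=cfg.n_samples)
    bmi = np.round(rng.normal(30.0, 6.0, size=cfg.n_samples), 1).clip(15, 60)
    log_hr = np.zeros(cfg.n_samples)
    for prot, lhr in cfg.hazards:
        log_hr += lhr * true_activity.loc[prot].to_numpy()
    hazard = cfg.baseline_hazard * np.exp(log_hr)
    event_time = rng.exponential(1.0 / hazard)
    censor_time = rng.uniform(0.0, cfg.censor_max_days, size=cfg.n_samples)
    os_time = np.minimum(event_time, censor_time)
    os_event = (event_time <= censor_time).astype(int)
    clinical = pd.DataFrame({
        "study": studies,
        "tissue": studies.map(lambda s: f"tissue_{s[-1]}"),
        "sample_type": "tumour",
        "age": age,
        "gender": gender,
        "bmi": bmi,
        "os_time_days": np.round(os_time, 1),
        "os_event": os_event,
        "subtype": blocks.map(lambda b: f"subtype{b}"),
    }, index=pd.Index(samples, name="sample_id"))

    truth = SyntheticTruth(
        true_activity=true_activity,
        true_effects=list(cfg.mutation_effects),
        true_hazards=list(cfg.hazards),
        cluster_labels=blocks,
    )
    cohort = Cohort(mrna, protein, phospho, cnv, mutation_records, clinical,
                    truth)

    # --- priors consistent with the planted wiring
    kinase_targets = {
        kin: {s: str(rng.choice(np.array(["database", "textmining"])))
              for s in ss}
        for kin, ss in kin_sites.items()
    }
    regulons = {
        tf: [(gene, mode, str(rng.choice(np.array(["A", "B", "C"]))))
             for gene, mode in targets]
        for tf, targets in tf_targets.items()
    }
    network = PriorNetwork(kinase_targets=kinase_targets, regulons=regulons)

    edges: dict[tuple[str, str], int] = {}
    for g, target, _ in cfg.mutation_effects:
        edges[(g, target)] = int(rng.integers(850, 1000))
    n_decoys = 10 * max(len(cfg.mutation_effects), 5)
    while sum(1 for s in edges.values() if s < 850) < n_decoys:
        a, b = rng.choice(genes, size=2, replace=False)
        key = (a, b) if a <= b else (b, a)
        if key not in edges:
            edges[key] = int(rng.integers(150, 850))
    edge_list = EdgeList(edges)

    regulated = [(kin, s) for kin in kinases for s in samples
                 if true_activity.loc[kin, s] != 0]
    order = rng.permutation(len(regulated))
    gold = [GoldStandardPair(*regulated[j]) for j in
            sorted(order[:min(cfg.n_gold_positives, len(regulated))].tolist())]

    priors = Priors(network=network, edges=edge_list, gold_standard=gold,
                    fasta=sequences)
    return Simulation(cohort=cohort, priors=priors)


def generate_cohort(config: SimConfig) -> Cohort:
    """Emit the multiomics matrices, mutations, clinical table and truth."""
    return simulate(config).cohort


def generate_priors(config: SimConfig) -> Priors:
    """Emit the prior network, edge list, gold standard and FASTA sequences."""
    return simulate(config).priors


# ---------------------------------------------------------------------------
# direct activity-scale simulators for recovery checks
# ---------------------------------------------------------------------------


def simulate_activity_given_mutations(
    n_samples: int,
    beta2: float,
    n_studies: int = 3,
    study_effect_sd: float = 0.5,
    noise_sd: float = 0.5,
    carrier_fraction: float = 0.3,
    seed: int = 0,
) -> tuple[pd.Series, pd.Series, pd.Series]:
    """Activity = study offset + beta2 * mutation + noise, on the score scale.

    Returns (activity, mutation indicator, study labels), all indexed by
    sample.  Used to check that the mutation-association model recovers a
    planted effect of known size.
    """
    rng = np.random.default_rng(seed)
    samples = [f"S{i:04d}" for i in range(1, n_samples + 1)]
    study = pd.Series([f"study{(i % n_studies) + 1}" for i in range(n_samples)],
                      index=samples)
    offsets = {f"study{j + 1}": rng.normal(0.0, study_effect_sd)
               for j in range(n_studies)}
    mut = pd.Series((rng.random(n_samples) < carrier_fraction).astype(int),
                    index=samples)
    activity = (study.map(offsets)
                + beta2 * mut
                + rng.normal(0.0, noise_sd, size=n_samples))
    return activity.astype(float), mut, study


def simulate_survival_from_activity(
    activity: pd.Series,
    log_hr: float,
    baseline_hazard: float = 1e-3,
    censor_max: float = 3000.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential survival with hazard = baseline * exp(log_hr * activity).

    Censoring is uniform on (0, censor_max).  Returns a frame with
    os_time_days and os_event indexed like `activity`.
    """
    rng = np.random.default_rng(seed)
    hazard = baseline_hazard * np.exp(log_hr * activity.to_numpy())
    event_time = rng.exponential(1.0 / hazard)
    censor_time = rng.uniform(0.0, censor_max, size=len(activity))
    return pd.DataFrame({
        "os_time_days": np.minimum(event_time, censor_time),
        "os_event": (event_time <= censor_time).astype(int),
    }, index=activity.index)
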