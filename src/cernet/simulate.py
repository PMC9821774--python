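"""Synthetic multi-tissue RNA-seq count simulation with planted ceRNA triads.

The generator emulates the statistical structure a ceRNA screen assumes:

* negative-binomial counts around log-normal per-feature baselines, with a
  single class-level dispersion and per-sample library sizes jittered
  uniformly within +/-20% of nominal;
* planted differentially expressed features whose between-condition mean
  ratio is ``2**de_log2fc_magnitude``;
* planted circRNA-miRNA-mRNA triads coupled through a per-sample latent
  factor added on the log2-mean scale — positive sign for the circRNA and
  mRNA, negative for the miRNA — so that, by construction, the miRNA is
  negatively co-expressed with both targets and the circRNA-mRNA pair is
  positively co-expressed;
* an interaction table containing the planted miRNA->target edges plus
  decoy edges sampled at a configurable density.

No sequences or reads are simulated: the unit is the count matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import RNA_CLASSES, ExpressionMatrix, GroundTruth
from .design import StudyDesign
from .errors import ConfigurationError

#: Library sizes are drawn uniformly within +/- this relative jitter.
LIBRARY_JITTER = 0.2

DEFAULT_N_FEATURES = {"circRNA": 300, "miRNA": 100, "mRNA": 500}


def _feature_ids(rna_class: str, n: int) -> list[str]:
    # Identifier styles follow bovine RNA-seq conventions (synthetic IDs).
    if rna_class == "circRNA":
        return [f"novel_circ_{i:06d}" for i in range(1, n + 1)]
    if rna_class == "miRNA":
        return [f"bta-miR-s{i:04d}" for i in range(1, n + 1)]
    return [f"ENSBTAG{i:011d}" for i in range(1, n + 1)]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic count generator.

    Parameters
    ----------
    n_features
        Features per RNA class (same feature set in every tissue).
    baseline_log_mean, baseline_log_sd
        Natural-log location/spread of the log-normal per-feature baseline
        mean expression. Defaults give a median mean of ~100 counts.
    dispersion
        NB dispersion phi; the NB size parameter is ``1/phi`` so that
        ``Var = mu + phi * mu**2``. Shared by all features of a run.
    de_fraction
        Fraction of each class planted as DE (per class dict or scalar).
    de_log2fc_magnitude
        |log2 fold change| planted on DE features (treatment over control).
    n_planted_triads
        Number of circRNA-miRNA-mRNA triads wired through a latent factor.
    triad_coupling_strength
        In (0, 1]; scales the latent factor for triad members.
    triad_latent_sd
        Standard deviation (log2 scale) of the shared latent factor at
        coupling 1. The latent is uniform on +/- sqrt(3) sd (bounded, so
        per-sample means have no lognormal heavy tail); the default makes
        the log-scale correlation between coupled partners ~0.96 at full
        coupling, well inside the |r| > 0.9 regime the screen filters on.
    interaction_density
        Probability that any non-planted (miRNA, target) combination is
        included as a decoy edge in the interaction table.
    triad_baseline_log_mean, triad_baseline_log_sd
        Baseline distribution (natural-log scale) for triad members.
        Sponge regulation is stoichiometric, so planted ceRNA partners
        are abundant transcripts (~1000 counts); this also keeps their
        counts clear of the zero-saturation regime across the latent
        factor's range.
    seed
        Seed for all randomness of the generator.
    """

    n_features: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_N_FEATURES))
    baseline_log_mean: float = math.log(100.0)
    baseline_log_sd: float = 1.0
    dispersion: float = 0.1
    de_fraction: float | dict[str, float] = 0.1
    de_log2fc_magnitude: float = 3.0
    n_planted_triads: int = 10
    triad_coupling_strength: float = 0.9
    triad_latent_sd: float = 2.5
    interaction_density: float = 0.05
    triad_baseline_log_mean: float = math.log(1000.0)
    triad_baseline_log_sd: float = 0.5
    seed: int = 0

    def de_fraction_of(self, rna_class: str) -> float:
        if isinstance(self.de_fraction, dict):
            return float(self.de_fraction.get(rna_class, 0.0))
        return float(self.de_fraction)

    def validate(self) -> None:
        for cls in RNA_CLASSES:
            if cls not in self.n_features or self.n_features[cls] <= 0:
                raise ConfigurationError(f"n_features[{cls!r}] must be a positive integer")
            frac = self.de_fraction_of(cls)
            if not 0.0 <= frac <= 1.0:
                raise ConfigurationError(f"de_fraction for {cls} must lie in [0, 1]")
        if self.dispersion <= 0:
            raise ConfigurationError("dispersion must be > 0")
        if self.de_log2fc_magnitude <= 0:
            raise ConfigurationError("de_log2fc_magnitude must be > 0")
        if self.n_planted_triads < 0:
            raise ConfigurationError("n_planted_triads must be >= 0")
        if self.n_planted_triads > min(self.n_features[c] for c in RNA_CLASSES):
            raise ConfigurationError(
                "n_planted_triads exceeds the smallest per-class feature count"
            )
        if not 0.0 < self.triad_coupling_strength <= 1.0 and self.n_planted_triads > 0:
            raise ConfigurationError("triad_coupling_strength must lie in (0, 1]")
        if not 0.0 <= self.interaction_density <= 1.0:
            raise ConfigurationError("interaction_density must lie in [0, 1]")


def _plant_truth(config: SimulationConfig, rng: np.random.Generator,
                 ids: dict[str, list[str]]) -> tuple[GroundTruth, dict[str, dict[str, int]]]:
    """Choose triad members and DE features; return truth and per-class DE signs."""
    triads: list[tuple[str, str, str]] = []
    members: dict[str, list[int]] = {}
    for cls in RNA_CLASSES:
        members[cls] = list(
            rng.choice(len(ids[cls]), size=config.n_planted_triads, replace=False)
        )
    for j in range(config.n_planted_triads):
        triads.append(
            (
                ids["circRNA"][members["circRNA"][j]],
                ids["miRNA"][members["miRNA"][j]],
                ids["mRNA"][members["mRNA"][j]],
            )
        )

    # Within a triad the circRNA and mRNA move together and the miRNA
    # opposes them; triad polarity alternates so that up- and down-shifted
    # mass stays balanced across conditions (keeps library composition,
    # hence CPM, stable under the planted effects).
    planted_de: set[tuple[str, str, str]] = set()
    signs: dict[str, dict[str, int]] = {cls: {} for cls in RNA_CLASSES}
    for cls in RNA_CLASSES:
        base_sign = -1 if cls == "miRNA" else +1
        for j, i in enumerate(members[cls]):
            polarity = +1 if j % 2 == 0 else -1
            sign = base_sign * polarity
            fid = ids[cls][i]
            planted_de.add((cls, fid, "up" if sign > 0 else "down"))
            signs[cls][fid] = sign
        forced = {ids[cls][i] for i in members[cls]}
        n_target = math.ceil(config.de_fraction_of(cls) * config.n_features[cls])
        extra_needed = max(0, n_target - len(forced))
        pool = [f for f in ids[cls] if f not in forced]
        if extra_needed > len(pool):
            extra_needed = len(pool)
        chosen = rng.choice(len(pool), size=extra_needed, replace=False) if extra_needed else []
        for i in chosen:
            direction = "up" if rng.random() < 0.5 else "down"
            planted_de.add((cls, pool[i], direction))
            signs[cls][pool[i]] = +1 if direction == "up" else -1

    planted_interactions = [
        edge
        for circ, mi, mrna in triads
        for edge in ((mi, circ, "circRNA"), (mi, mrna, "mRNA"))
    ]
    truth = GroundTruth(
        planted_de=planted_de,
        planted_triads=triads,
        planted_interactions=planted_interactions,
    )
    truth.validate()
    return truth, signs


def simulate_counts(
    design: StudyDesign, config: SimulationConfig
) -> tuple[dict[tuple[str, str], ExpressionMatrix], GroundTruth]:
    """Simulate count matrices for every (RNA class, tissue) of the design.

    Returns
    -------
    matrices
        Mapping ``(rna_class, tissue) -> ExpressionMatrix``.
    truth
        The planted ground truth (shared across tissues: the same features
        are DE and the same triads are coupled in every tissue).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    ids = {cls: _feature_ids(cls, config.n_features[cls]) for cls in RNA_CLASSES}
    truth, signs = _plant_truth(config, rng, ids)

    # Per-feature baselines, shared across tissues.
    log2_base = {
        cls: (config.baseline_log_mean
              + config.baseline_log_sd * rng.standard_normal(config.n_features[cls])
              ) / math.log(2.0)
        for cls in RNA_CLASSES
    }
    triad_index = {
        cls: [ids[cls].index(triad[pos]) for triad in truth.planted_triads]
        for pos, cls in ((0, "circRNA"), (1, "miRNA"), (2, "mRNA"))
    }
    # Triad members are abundant transcripts: redraw their baselines.
    for cls in RNA_CLASSES:
        for i in triad_index[cls]:
            log2_base[cls][i] = (
                config.triad_baseline_log_mean
                + config.triad_baseline_log_sd * rng.standard_normal()
            ) / math.log(2.0)
    latent_sign = {"circRNA": +1.0, "miRNA": -1.0, "mRNA": +1.0}

    r = 1.0 / config.dispersion
    matrices: dict[tuple[str, str], ExpressionMatrix] = {}
    for tissue in design.tissues:
        meta = design.samples(tissue)
        n_samp = len(meta)
        # DE effects are planted symmetrically about the baseline
        # (-delta/2 in control, +delta/2 in treatment) so a feature's mean
        # ratio is 2**delta while total library mass stays balanced.
        half_effect = (meta["condition"] == design.treatment).to_numpy(dtype=float) - 0.5
        lib = rng.uniform(1.0 - LIBRARY_JITTER, 1.0 + LIBRARY_JITTER, size=n_samp)
        # Unit-sd uniform latent, bounded at +/- sqrt(3).
        bound = math.sqrt(3.0)
        latent = rng.uniform(-bound, bound, size=(config.n_planted_triads, n_samp))
        amp = config.triad_coupling_strength * config.triad_latent_sd
        # E[2**(amp U)] = sinh(k)/k with k = amp*sqrt(3)*ln2; subtracting
        # its log2 keeps the coupled features' mean at their baseline.
        k = amp * bound * math.log(2.0)
        latent_mean_corr = math.log2(math.sinh(k) / k) if k > 0 else 0.0
        for cls in RNA_CLASSES:
            n_feat = config.n_features[cls]
            log2_mu = np.tile(log2_base[cls][:, None], (1, n_samp))
            for fid, sign in signs[cls].items():
                i = ids[cls].index(fid)
                log2_mu[i] += sign * config.de_log2fc_magnitude * half_effect
            for j, i in enumerate(triad_index[cls]):
                log2_mu[i] += latent_sign[cls] * amp * latent[j] - latent_mean_corr
            mu = np.exp2(log2_mu) * lib[None, :]
            counts = rng.negative_binomial(r, r / (r + mu), size=(n_feat, n_samp))
            matrices[(cls, tissue)] = ExpressionMatrix(
                counts=pd.DataFrame(counts, index=ids[cls], columns=meta["sample_id"].tolist()),
                rna_class=cls,
                tissue=tissue,
            )
    return matrices, truth


def generate_interactions(
    truth: GroundTruth,
    config: SimulationConfig,
    feature_ids: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Interaction table: planted edges plus density-sampled decoys.

    Parameters
    ----------
    truth
        Ground truth from :func:`simulate_counts`.
    config
        Simulation configuration (``interaction_density``, ``seed``).
    feature_ids
        Per-class feature ID lists to draw decoys from. Defaults to the
        ID space implied by ``config.n_features``.

    Returns
    -------
    DataFrame with columns ``mirna_id``, ``target_id``, ``target_type``;
    rows unique, deterministically sorted.
    """
    config.validate()
    if feature_ids is None:
        feature_ids = {cls: _feature_ids(cls, config.n_features[cls]) for cls in RNA_CLASSES}
    rng = np.random.default_rng([config.seed, 7])

    rows = [
        {"mirna_id": mi, "target_id": tgt, "target_type": ttype}
        for mi, tgt, ttype in truth.planted_interactions
    ]
    planted = set(truth.planted_interactions)
    mirnas = feature_ids["miRNA"]
    if config.interaction_density > 0:
        for ttype in ("circRNA", "mRNA"):
            targets = feature_ids[ttype]
            mask = rng.random((len(mirnas), len(targets))) < config.interaction_density
            mi_idx, tgt_idx = np.nonzero(mask)
            for a, b in zip(mi_idx, tgt_idx):
                edge = (mirnas[a], targets[b], ttype)
                if edge not in planted:
                    rows.append(
                        {"mirna_id": edge[0], "target_id": edge[1], "target_type": ttype}
                    )
    table = pd.DataFrame(rows, columns=["mirna_id", "target_id", "target_type"])
    table = table.drop_duplicates().sort_values(
        ["target_type", "mirna_id", "target_id"], ignore_index=True
    )
    return table
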