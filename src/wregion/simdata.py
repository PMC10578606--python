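"""Synthetic data generators with the statistical structure the analysis assumes.

Three generators make every downstream stage testable without any sequencing
download:

* :func:`simulate_counts` draws a gene x sample negative-binomial count
  matrix shaped like the tadpole gonad experiment: wildtype females (the
  reference), wildtype males carrying sex-biased expression on a designated
  gene panel, and knockout females whose panel shifts are a tunable fraction
  ``m`` of the male shifts (the masculinization coefficient), plus clutch
  (batch) offsets and library-size variation. The ground truth is returned
  alongside the counts for parameter-recovery tests.
* :func:`simulate_cross_offspring` draws brood genotype counts multinomially
  from the exact Mendelian W/W*/Z cross distribution.
* :func:`simulate_tip_states` places a single locus gain on a tree node and
  loses it independently on each descendant edge, generating presence/absence
  patterns for testing Dollo inference.

All three are bitwise reproducible under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .counts_de import CountMatrix
from .crosses import offspring_genotype_distribution, parse_genotype
from .wphylo import ABSENT, PRESENT, Tree

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_counts",
    "simulate_cross_offspring",
    "simulate_tip_states",
    "write_simulation",
    "GROUP_METADATA",
]

#: Genotype / phenotype labels attached to the three canonical group kinds.
GROUP_METADATA = {
    "wt_female": {"genotype": "WZ", "phenotype": "female"},
    "wt_male": {"genotype": "ZZ", "phenotype": "male"},
    "ko_female": {"genotype": "W*Z", "phenotype": "male"},
}


def _group_kind(group: str) -> str:
    """Classify a group label by prefix.

    ``wt_male*`` groups carry the sex-biased panel effect, ``ko_*`` groups the
    knockout (masculinized) effect, and every other label sits at baseline —
    so e.g. ``wt_female_mf`` provides an independent-clutch female reference
    with no shared samples with ``wt_female``.
    """
    if group.startswith("wt_male"):
        return "wt_male"
    if group.startswith("ko_"):
        return "ko_female"
    return "wt_female"


def _default_group_sizes() -> dict[str, int]:
    return {"wt_female": 6, "wt_male": 6, "ko_female": 6}


@dataclass
class SimConfig:
    """Parameters of the count simulator.

    Defaults mirror the experimental design the package targets: groups of
    six (knockout line and the largest wildtype male/female clutch), a
    74-gene sex-related panel, panel effect sizes |log2FC| ~ |N(1.5, 0.5)|
    with random sign, and three clutch-like batches.

    Parameters
    ----------
    n_genes, panel_size
        Total simulated genes and the number carrying sex-biased expression.
    group_sizes
        Samples per group label; the canonical labels are ``wt_female``,
        ``wt_male`` and ``ko_female``.
    baseline_log2_mean, baseline_log2_sd
        Per-gene baseline expression on the log2 scale, N(mean, sd).
    dispersion
        NB dispersion phi (var = mu + phi mu^2). A scalar applies to every
        gene; a ``(shape, scale)`` tuple draws per-gene phi from a gamma.
    sex_effect_mean, sex_effect_sd
        |log2FC| of panel genes in the wt_male vs wt_female contrast is
        |N(mean, sd)|; the sign is random per gene.
    masc_coefficient
        m in [0, 1]: knockout-female panel log2FC = m x male log2FC plus
        N(0, ko_noise_sd) noise. m = 0 means no masculinization.
    batch_sd
        SD of the additive per-batch log2 offset shared by all genes.
    libsize_log_sd
        SD of the per-sample natural-log library-size factor.
    seed
        Top-level integer seed; all randomness derives from it.
    """

    n_genes: int = 2000
    panel_size: int = 74
    group_sizes: Mapping[str, int] = field(default_factory=_default_group_sizes)
    baseline_log2_mean: float = 6.0
    baseline_log2_sd: float = 2.0
    dispersion: "float | tuple[float, float]" = 0.1
    sex_effect_mean: float = 1.5
    sex_effect_sd: float = 0.5
    masc_coefficient: float = 0.8
    ko_noise_sd: float = 0.1
    batch_sd: float = 0.3
    n_batches: int = 3
    libsize_log_sd: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1 or self.panel_size < 1:
            raise ValueError("n_genes and panel_size must be positive")
        if self.panel_size > self.n_genes:
            raise ValueError("panel_size cannot exceed n_genes")
        if not self.group_sizes or any(n < 1 for n in self.group_sizes.values()):
            raise ValueError("each group needs at least one sample")
        for name in ("baseline_log2_sd", "sex_effect_sd", "ko_noise_sd",
                     "batch_sd", "libsize_log_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if isinstance(self.dispersion, tuple):
            shape, scale = self.dispersion
            if shape <= 0 or scale <= 0:
                raise ValueError("gamma dispersion needs positive shape and scale")
        elif self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if not 0.0 <= self.masc_coefficient <= 1.0:
            raise ValueError("masc_coefficient must lie in [0, 1]")
        if self.n_batches < 1:
            raise ValueError("n_batches must be positive")

    @classmethod
    def from_json(cls, path) -> "SimConfig":
        with open(path) as fh:
            data = json.load(fh)
        if "dispersion" in data and isinstance(data["dispersion"], list):
            data["dispersion"] = tuple(data["dispersion"])
        return cls(**data)


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset, indexed like the count matrix."""

    panel_genes: tuple[str, ...]
    true_sex_log2fc: pd.Series
    true_ko_log2fc: pd.Series
    size_factors: pd.Series
    batch_offsets: pd.Series
    dispersion: pd.Series

    def to_json(self, path) -> None:
        payload = {
            "panel_genes": list(self.panel_genes),
            "true_sex_log2fc": self.true_sex_log2fc.to_dict(),
            "true_ko_log2fc": self.true_ko_log2fc.to_dict(),
            "size_factors": self.size_factors.to_dict(),
            "batch_offsets": self.batch_offsets.to_dict(),
            "dispersion": self.dispersion.to_dict(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def simulate_counts(config: SimConfig) -> tuple[CountMatrix, SimTruth]:
    """Simulate a NB count matrix plus its ground truth.

    Per gene g and sample j the NB mean is
    ``2^(baseline_g + effect_{g, group(j)} + batch_offset_{batch(j)}) * s_j``
    with ``s_j`` the log-normal library-size factor, and counts are NB with
    variance ``mu + phi mu^2`` (Poisson when phi = 0). Samples are assigned
    round-robin to batches within each group, so batches mix groups the way
    clutches mix sexes.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    panel_idx = np.sort(
        rng.choice(config.n_genes, size=config.panel_size, replace=False)
    )
    panel_genes = tuple(genes[i] for i in panel_idx)

    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd,
                          size=config.n_genes)

    sex_fc = np.zeros(config.n_genes)
    magnitudes = np.abs(rng.normal(config.sex_effect_mean, config.sex_effect_sd,
                                   size=config.panel_size))
    signs = rng.choice([-1.0, 1.0], size=config.panel_size)
    sex_fc[panel_idx] = signs * magnitudes

    ko_fc = np.zeros(config.n_genes)
    ko_fc[panel_idx] = (
        config.masc_coefficient * sex_fc[panel_idx]
        + rng.normal(0.0, config.ko_noise_sd, size=config.panel_size)
    )

    if isinstance(config.dispersion, tuple):
        shape, scale = config.dispersion
        phi = rng.gamma(shape, scale, size=config.n_genes)
    else:
        phi = np.full(config.n_genes, float(config.dispersion))

    sample_ids: list[str] = []
    groups: list[str] = []
    batches: list[str] = []
    for group, n in config.group_sizes.items():
        for i in range(n):
            sample_ids.append(f"{group}_{i + 1:02d}")
            groups.append(group)
            batches.append(f"b{(i % config.n_batches) + 1}")
    n_samples = len(sample_ids)

    batch_labels = [f"b{i + 1}" for i in range(config.n_batches)]
    batch_off = rng.normal(0.0, config.batch_sd, size=config.n_batches)
    batch_of_sample = np.array([batch_labels.index(b) for b in batches])

    size_factors = np.exp(rng.normal(0.0, config.libsize_log_sd, size=n_samples))

    effect = np.zeros((config.n_genes, n_samples))
    for j, group in enumerate(groups):
        kind = _group_kind(group)
        if kind == "wt_male":
            effect[:, j] = sex_fc
        elif kind == "ko_female":
            effect[:, j] = ko_fc
        # female reference groups sit at baseline

    log2_mu = baseline[:, None] + effect + batch_off[batch_of_sample][None, :]
    mu = np.exp2(log2_mu) * size_factors[None, :]

    counts = np.empty(mu.shape, dtype=np.int64)
    phi_col = phi[:, None]
    poisson_rows = phi == 0
    if poisson_rows.any():
        counts[poisson_rows] = rng.poisson(mu[poisson_rows])
    nb_rows = ~poisson_rows
    if nb_rows.any():
        r = 1.0 / phi_col[nb_rows]
        p = r / (r + mu[nb_rows])
        counts[nb_rows] = rng.negative_binomial(r, p)

    meta = pd.DataFrame(
        {
            "group": groups,
            "genotype": [GROUP_METADATA[_group_kind(g)]["genotype"] for g in groups],
            "phenotype": [GROUP_METADATA[_group_kind(g)]["phenotype"] for g in groups],
            "batch": batches,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    cm = CountMatrix(pd.DataFrame(counts, index=genes, columns=sample_ids), meta)
    truth = SimTruth(
        panel_genes=panel_genes,
        true_sex_log2fc=pd.Series(sex_fc, index=genes, name="true_sex_log2fc"),
        true_ko_log2fc=pd.Series(ko_fc, index=genes, name="true_ko_log2fc"),
        size_factors=pd.Series(size_factors, index=sample_ids, name="size_factor"),
        batch_offsets=pd.Series(batch_off, index=batch_labels, name="batch_offset"),
        dispersion=pd.Series(phi, index=genes, name="dispersion"),
    )
    return cm, truth


def simulate_cross_offspring(
    mother, father, n: int, seed: "int | None" = 0
) -> dict[str, int]:
    """Multinomial brood draw from the exact Mendelian cross distribution."""
    if n < 0:
        raise ValueError("offspring count must be non-negative")
    dist = offspring_genotype_distribution(parse_genotype(mother), parse_genotype(father))
    classes = list(dist.classes)
    probs = [float(dist.probs[c]) for c in classes]
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(n, probs) if n > 0 else np.zeros(len(classes), dtype=int)
    return {c: int(k) for c, k in zip(classes, draws)}


def simulate_tip_states(
    tree: Tree, gain_node: str, loss_prob: float, seed: "int | None" = 0
) -> dict[str, str]:
    """Simulate presence/absence tip states under single-gain Dollo evolution.

    The locus is present at ``gain_node`` and lost independently with
    probability ``loss_prob`` on every edge below it (loss is irreversible);
    tips outside the gain clade are absent.
    """
    if not 0.0 <= loss_prob <= 1.0:
        raise ValueError("loss_prob must lie in [0, 1]")
    tree._node(gain_node)  # KeyError for unknown ids
    rng = np.random.default_rng(seed)

    lost: dict[str, bool] = {gain_node: False}
    for nid in tree.preorder(gain_node):
        if nid == gain_node:
            continue
        parent = tree.parent(nid)
        lost[nid] = lost[parent] or (rng.random() < loss_prob)

    clade = set(tree.preorder(gain_node))
    states: dict[str, str] = {}
    for tip in tree.tip_names():
        if tip in clade and not lost[tip]:
            states[tip] = PRESENT
        else:
            states[tip] = ABSENT
    return states


def write_simulation(out_dir, cm: CountMatrix, truth: SimTruth,
                     config: "SimConfig | None" = None) -> None:
    """Write counts.tsv, samples.tsv, truth.json (and config.json) to a directory."""
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cm.to_tsv(out / "counts.tsv", out / "samples.tsv")
    truth.to_json(out / "truth.json")
    if config is not None:
        payload = dataclasses.asdict(config)
        payload["group_sizes"] = dict(payload["group_sizes"])
        with open(out / "config.json", "w") as fh:
            json.dump(payload, fh, indent=1)
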