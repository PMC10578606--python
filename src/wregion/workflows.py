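"""End-to-end conveniences tying the simulator to the analysis stages."""

from __future__ import annotations

from .counts_de import ContrastResult, ContrastSpec, nb_two_group_test
from .masc import GenePanel
from .simdata import SimConfig, SimTruth, simulate_counts

__all__ = ["simulate_masc_pair"]


def simulate_masc_pair(
    seed: int,
    masc_coefficient: float = 0.8,
    n_per_group: int = 6,
    n_genes: int = 2000,
    panel_size: int = 74,
    **config_overrides,
) -> tuple[ContrastResult, ContrastResult, GenePanel, SimTruth]:
    """Simulate one knockout experiment and run its two contrasts.

    Emulates the comparison design of the motivating study: the knockout
    contrast (``ko_female`` vs its wildtype sisters ``wt_female``) and the
    sex-biased contrast (``wt_male`` vs ``wt_female_mf``) draw their female
    references from independent clutches, so the two fold-change vectors
    share no samples.

    Returns the knockout ContrastResult, the male/female ContrastResult, the
    true sex-related gene panel, and the simulation ground truth.
    """
    config = SimConfig(
        seed=seed,
        masc_coefficient=masc_coefficient,
        n_genes=n_genes,
        panel_size=panel_size,
        group_sizes={
            "wt_female": n_per_group,
            "ko_female": n_per_group,
            "wt_male": n_per_group,
            "wt_female_mf": n_per_group,
        },
        **config_overrides,
    )
    cm, truth = simulate_counts(config)
    ko = nb_two_group_test(cm, ContrastSpec("ko_female", "wt_female"))
    mf = nb_two_group_test(cm, ContrastSpec("wt_male", "wt_female_mf"))
    return ko, mf, GenePanel(truth.panel_genes, name="simulated_panel"), truth
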