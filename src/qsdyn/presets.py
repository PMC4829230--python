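"""Standard study configurations.

Two regimes are distinguished by the effective autoinducer diffusivity:

* **Planktonic / well-stirred** (swimming cells in liquid): the
  molecular diffusivity from the Wilke-Chang correlation (~1.1e3
  um^2/s), under which the extracellular field mixes across the domain
  within seconds and activation order is set by each cell's parameters.
* **Colony on a surface** (growth-driven motion only): a hindered
  effective diffusivity of 18 um^2/s, representing transport through the
  colony/substratum boundary layer. Colony-scale autoinducer gradients
  then persist against growth, which is the regime in which LuxIR
  activation nucleates where residence time is longest (the colony
  center) and spreads as an outward wave, and in which no-flux
  boundaries visibly skew where activation begins.

The reduced domains here (80-100 um, tens of founder cells) compress
the full 500-um study so that one run takes seconds; cell density is
correspondingly higher than the OD-derived full-scale value, which
moves activation earlier but preserves the mechanisms under study.
"""

from __future__ import annotations

from .engine import RunConfig
from .environment import GridSpec
from .lsr_model import LsrParams
from .luxir_model import LuxParams
from .population import GrowthSpec, HeterogeneitySpec

__all__ = [
    "HINDERED_D",
    "swim_lsr",
    "colony_lsr",
    "colony_lux",
    "motility_pair",
    "full_scale_lsr",
]

#: effective autoinducer diffusivity inside a surface-attached colony
#: (um^2/s); config-exposed, see module docstring
HINDERED_D = 18.0
#: diffusivity used for the LuxIR wave study (stronger colony-scale
#: gradients push the activation origin toward the colony center)
LUX_WAVE_D = 6.0
#: diffusivity for the motility-mode comparison: slow enough that the
#: packed colony holds gradients, fast enough that dispersed swimmers
#: share one pool
MOTILITY_STUDY_D = 1.0


def swim_lsr(
    sigma: float = 0.0,
    target: str = "basal",
    seed: int = 0,
    t_end: float = 170.0,
    log_base: str = "e",
    n_initial: int = 40,
    lsr: LsrParams | None = None,
) -> RunConfig:
    """Reduced swimming-cell Lsr run (heterogeneity sweeps)."""
    lsr = lsr or LsrParams()
    medians = {"basal": lsr.basal, "K_synth": lsr.K_synth, "V_ydgG": lsr.V_ydgG}
    return RunConfig(
        model="lsr",
        motility="swim",
        grid=GridSpec(Lx=100.0, Ly=100.0, dx=4.0, dt_engine=1.0),
        heterogeneity=HeterogeneitySpec(
            target=target,
            median=medians[target],
            sigma=sigma,
            log_base=log_base,
            seed=seed,
        ),
        growth=GrowthSpec(),
        lsr=lsr,
        n_initial=n_initial,
        t_end=t_end,
        seed=seed,
    )


def colony_lsr(
    sigma: float = 0.0225,
    seed: int = 0,
    t_end: float = 220.0,
    log_base: str = "10",
    n_initial: int = 30,
) -> RunConfig:
    """Reduced Lsr colony-growth run (dispersed "speckled" activation).

    The default heterogeneity is the basal-import distribution with
    median 487.8 uM/min and a CV of 0.052 (sigma 0.0225 on the base-10
    logarithm).
    """
    return RunConfig(
        model="lsr",
        motility="colony",
        grid=GridSpec(Lx=80.0, Ly=80.0, dx=4.0, dt_engine=1.0, D=HINDERED_D),
        heterogeneity=HeterogeneitySpec(
            target="basal", median=487.8, sigma=sigma, log_base=log_base, seed=seed
        ),
        growth=GrowthSpec(),
        n_initial=n_initial,
        t_end=t_end,
        seed=seed,
    )


def colony_lux(
    sigma: float = 0.0225,
    seed: int = 0,
    t_end: float = 330.0,
    log_base: str = "10",
    n_initial: int = 30,
) -> RunConfig:
    """Reduced LuxIR colony-growth run (outward activation wave).

    One cell per 2-um element, as in the full-scale geometry, so that
    the colony's local AHL source density sustains the center-out
    activation pattern.
    """
    return RunConfig(
        model="luxir",
        motility="colony",
        grid=GridSpec(Lx=80.0, Ly=80.0, dx=2.0, dt_engine=1.0, D=LUX_WAVE_D),
        heterogeneity=HeterogeneitySpec(
            target="r_basal", median=1.0, sigma=sigma, log_base=log_base, seed=seed
        ),
        growth=GrowthSpec(),
        n_initial=n_initial,
        t_end=t_end,
        seed=seed,
    )


def motility_pair(seed: int = 0, t_end: float = 150.0) -> tuple[RunConfig, RunConfig]:
    """Matched (colony, swim) Lsr configurations for the motility study.

    A 200-um domain leaves a scale gap between the swimmers' spacing
    (~20 um, well mixed at the study diffusivity) and the colony radius
    (gradients persist), which is what makes the packed colony activate
    earlier and freeze at a lower activated fraction.
    """
    base = RunConfig(
        model="lsr",
        motility="colony",
        grid=GridSpec(Lx=200.0, Ly=200.0, dx=4.0, dt_engine=1.0, D=MOTILITY_STUDY_D),
        heterogeneity=HeterogeneitySpec(
            target="basal", median=487.8, sigma=0.0225, log_base="10", seed=seed
        ),
        growth=GrowthSpec(),
        n_initial=100,
        t_end=t_end,
        seed=seed,
    )
    return base, base.model_copy(update={"motility": "swim"})


def full_scale_lsr(seed: int = 0, **overrides) -> RunConfig:
    """The full 500 x 500 um study configuration (36 founder cells,
    0.0667 s master steps). Provided for completeness; hours of compute."""
    cfg = RunConfig(
        model="lsr",
        motility="swim",
        grid=GridSpec(),
        heterogeneity=HeterogeneitySpec(
            target="basal", median=487.8, sigma=0.0225, log_base="10", seed=seed
        ),
        growth=GrowthSpec(),
        seed=seed,
    )
    return cfg.model_copy(update=overrides) if overrides else cfg
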