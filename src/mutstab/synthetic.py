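"""Seeded generators emulating the statistical structure of the real inputs.

The ΔΔG generator produces a near-zero bulk plus a destabilizing tail
(heavier for buried positions, with an extra penalty for substitutions to
proline); phenotypes follow the two-state model with multiplicative noise;
labels are thresholded true ΔΔG with independent flips; allele frequencies
decay with destabilization. Every generator is a pure function of its
configuration, whose mandatory seed makes all output reproducible. The
parameters are synthetic study conditions, not values fitted to any real
dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .thermo import GAS_CONSTANT_KCAL, T_37C, ThermoModel
from .variants import AMINO_ACIDS, DdgMatrix, VariantKey, saturation_keys

__all__ = [
    "SyntheticConfig",
    "gen_ddg_matrix",
    "gen_phenotypes",
    "gen_labels",
    "gen_frequencies",
    "gen_potts_truth",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic pipeline (all rates/sizes in one place)."""

    seed: int
    n_positions: int = 120
    burial_fraction: float = 0.35
    # two-component ΔΔG mixture (kcal/mol): near-zero bulk + destabilizing tail
    bulk_mean: float = 0.5
    bulk_sd: float = 0.8
    tail_shape: float = 2.0
    tail_scale: float = 3.0
    tail_shift: float = 2.0
    tail_prob_buried: float = 0.35
    tail_prob_exposed: float = 0.08
    proline_penalty: float = 2.0
    # two-state model truth and noise
    dg_wt_true: float = -3.0
    level_noise_sigma: float = 0.15  # lognormal sd on relative abundance
    survival_noise_sd: float = 5.0  # additive sd, percentage points
    s_folded: float = 0.0  # functional (folded) cells die under the drug
    s_unfolded: float = 100.0
    halflife_wt_h: float = 19.0
    halflife_floor: float = 0.15
    halflife_noise_sigma: float = 0.1
    # pathogenicity labels
    label_threshold: float = 3.0
    label_noise: float = 0.1
    # allele-frequency model: E[log10 f] decreases with destabilization
    freq_log10_base: float = -2.5
    freq_slope: float = 0.6
    freq_noise_sd: float = 0.5
    temperature: float = T_37C

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        for name in ("burial_fraction", "tail_prob_buried", "tail_prob_exposed", "label_noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    def thermo_model(self) -> ThermoModel:
        return ThermoModel(self.dg_wt_true, GAS_CONSTANT_KCAL, self.temperature)

    def to_dict(self) -> dict:
        return asdict(self)


def _rng(config: SyntheticConfig, stream: str) -> np.random.Generator:
    """Independent, reproducible stream per generator (stable across processes)."""
    import zlib

    return np.random.default_rng([config.seed, zlib.crc32(stream.encode()) % (2**31)])


def gen_ddg_matrix(config: SyntheticConfig) -> DdgMatrix:
    """Full saturation matrix (19 substitutions × n_positions).

    Buried positions draw from the destabilizing gamma tail with higher
    probability; substitutions to proline get an additive penalty.
    """
    rng = _rng(config, "ddg")
    wt_seq = "".join(rng.choice(list(AMINO_ACIDS), size=config.n_positions))
    buried = rng.random(config.n_positions) < config.burial_fraction
    keys = saturation_keys(wt_seq)
    values: dict[VariantKey, float] = {}
    for key in keys:
        p_tail = config.tail_prob_buried if buried[key.position - 1] else config.tail_prob_exposed
        if rng.random() < p_tail:
            ddg = config.tail_shift + rng.gamma(config.tail_shape, config.tail_scale)
        else:
            ddg = rng.normal(config.bulk_mean, config.bulk_sd)
        if key.mut_aa == "P":
            ddg += config.proline_penalty
        values[key] = float(ddg)
    return DdgMatrix(values, provenance=f"synthetic(seed={config.seed})")


def _subset_frame(matrix: DdgMatrix, subset=None) -> pd.DataFrame:
    s = matrix.to_series()
    if subset is not None:
        s = s.loc[[str(k) for k in subset]]
    return s.rename_axis("variant").reset_index()


def gen_phenotypes(matrix: DdgMatrix, config: SyntheticConfig, subset=None) -> pd.DataFrame:
    """Per-variant levels, half-lives, survival and interaction categories.

    Levels are the two-state prediction times lognormal noise; survival is
    the anchored interpolation plus clipped Gaussian noise; half-life is a
    monotone map of the folded fraction, t½ = t½_WT·(floor + (1−floor)·level),
    with lognormal noise. ``subset`` restricts to the given variant keys.
    """
    rng = _rng(config, "phenotypes")
    df = _subset_frame(matrix, subset)
    model = config.thermo_model()
    level_pred = model.predicted_level(df["ddg"].to_numpy())

    noise = rng.lognormal(mean=0.0, sigma=config.level_noise_sigma, size=len(df)) \
        if config.level_noise_sigma > 0 else np.ones(len(df))
    df["level"] = level_pred * noise

    surv = config.s_unfolded + (config.s_folded - config.s_unfolded) * level_pred
    if config.survival_noise_sd > 0:
        surv = surv + rng.normal(0.0, config.survival_noise_sd, size=len(df))
    df["survival_pct"] = np.clip(surv, 0.0, 100.0)

    hl = config.halflife_wt_h * (config.halflife_floor + (1.0 - config.halflife_floor) * level_pred)
    if config.halflife_noise_sigma > 0:
        hl = hl * rng.lognormal(0.0, config.halflife_noise_sigma, size=len(df))
    df["half_life_h"] = hl
    df["half_life_sd"] = 0.1 * hl

    ddg = df["ddg"].to_numpy()
    df["msh6_interaction"] = np.where(ddg > 15, "no", np.where(ddg > 8, "weak", "yes"))
    df["nuclear"] = "yes"
    df["patient_found"] = False
    return df


def gen_labels(matrix: DdgMatrix, config: SyntheticConfig, subset=None) -> pd.DataFrame:
    """Pathogenic iff true ΔΔG exceeds the threshold, then noisy label flips."""
    rng = _rng(config, "labels")
    df = _subset_frame(matrix, subset)
    pathogenic = df["ddg"].to_numpy() > config.label_threshold
    flips = rng.random(len(df)) < config.label_noise
    pathogenic = pathogenic ^ flips
    df["label"] = np.where(pathogenic, "pathogenic", "non_pathogenic")
    df["source"] = "synthetic"
    return df[["variant", "label", "source"]]


def gen_frequencies(matrix: DdgMatrix, config: SyntheticConfig, subset=None) -> pd.DataFrame:
    """Allele frequencies whose expected log10 decreases with destabilization."""
    rng = _rng(config, "frequencies")
    df = _subset_frame(matrix, subset)
    log10f = (
        config.freq_log10_base
        - config.freq_slope * np.clip(df["ddg"].to_numpy(), 0.0, None)
        + rng.normal(0.0, config.freq_noise_sd, size=len(df))
    )
    df["allele_frequency"] = np.clip(10.0 ** log10f, 0.0, 1.0)
    return df[["variant", "allele_frequency"]]


def gen_potts_truth(
    length: int = 8,
    alphabet: str = "ACDE",
    field_scale: float = 1.0,
    coupled_pair: tuple[int, int] | None = (2, 5),
    coupling_strength: float = 1.6,
    seed: int = 0,
):
    """A known small fields+couplings model for parameter-recovery experiments.

    Fields are i.i.d. normal; one column pair (if given) carries a strong
    coupling block favouring matched states, all other couplings are zero.
    Returned in the zero-sum gauge.
    """
    from .potts import PottsModel

    rng = np.random.default_rng(seed)
    q = len(alphabet)
    h = rng.normal(0.0, field_scale, size=(length, q))
    J = np.zeros((length, length, q, q))
    if coupled_pair is not None:
        i, j = coupled_pair
        block = coupling_strength * (2.0 * np.eye(q) - 1.0)  # favour matching states
        J[i, j] = block
        J[j, i] = block.T
    return PottsModel(h, J, alphabet, meta={"synthetic": True, "seed": seed}).to_zero_sum()
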