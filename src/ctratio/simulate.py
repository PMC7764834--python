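"""Synthetic bone-marrow Ct cohorts with the structure the pipeline assumes.

The generative model for sample i and marker j is

    Ct_ij = base_j + shift(j, group_i) + offset_i + eps_ij

with offset_i ~ N(0, tau^2) a per-sample loading/input offset (it cancels
in every ratio variable up to the nf3 caveat discussed in the methods
note) and eps_ij ~ N(0, sigma^2) independent Ct measurement noise.  Group
shifts are in PCR cycles: a shift of -1 doubles the marker's concentration
in that group under ideal efficiency.

Defaults mirror the study cohort: 48 NTP / 22 ALL / 44 AML (114 samples),
sigma = 0.5 cycles, tau = 1.0 cycles, and planted shifts of 1.5-2.5 cycles
on a handful of markers matching the direction of the strongest reported
group differences.  Reference miRNAs receive no group effects — that is
what makes them references.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .panel import GROUPS, CtMatrix, MarkerPanel

#: Study cohort sizes.
DEFAULT_GROUP_SIZES: dict[str, int] = {"NTP": 48, "ALL": 22, "AML": 44}

DEFAULT_NOISE_SD = 0.5    # Ct measurement noise sigma, cycles
DEFAULT_LOADING_SD = 1.0  # per-sample loading offset tau, cycles


def default_base_ct(panel: MarkerPanel) -> dict[str, float]:
    """Fixed per-marker baseline Cts spread over [20, 34] cycles.

    Values follow a deterministic low-discrepancy spacing of the panel
    order, so every marker has a distinct, reproducible baseline; the
    particular values are irrelevant downstream because ratio variables
    subtract them out per pair.
    """
    markers = panel.markers
    phi = 0.6180339887498949
    return {m: round(20.0 + 14.0 * ((phi * (i + 1)) % 1.0), 2)
            for i, m in enumerate(markers)}


#: Planted group shifts (marker, group, cycles) used as the default study
#: condition: miR-150 depleted in both leukemias, miR-223 depleted in ALL,
#: miR-100 enriched in ALL, miR-221 enriched in AML (positive shift = higher
#: Ct = lower concentration).
DEFAULT_EFFECTS: tuple[tuple[str, str, float], ...] = (
    ("miR-150", "ALL", 2.0),
    ("miR-150", "AML", 2.0),
    ("miR-223", "ALL", 2.0),
    ("miR-100", "ALL", -2.0),
    ("miR-221", "AML", -1.5),
)


@dataclass
class SyntheticConfig:
    """Parameters of the Ct cohort generator."""

    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    base_ct: Mapping[str, float] | None = None
    effects: Sequence[tuple[str, str, float]] = DEFAULT_EFFECTS
    noise_sd: float = DEFAULT_NOISE_SD
    loading_sd: float = DEFAULT_LOADING_SD
    seed: int | None = None

    def validate(self, panel: MarkerPanel) -> None:
        for group, size in self.group_sizes.items():
            if group not in GROUPS:
                raise ConfigError(f"unknown group {group!r}")
            if size < 0:
                raise ConfigError("group sizes must be >= 0")
        if self.noise_sd < 0 or self.loading_sd < 0:
            raise ConfigError("noise_sd and loading_sd must be >= 0")
        for marker, group, shift in self.effects:
            if marker not in panel.markers:
                raise ConfigError(f"effect references unknown marker {marker!r}")
            if group not in GROUPS:
                raise ConfigError(f"effect references unknown group {group!r}")
            if not np.isfinite(shift):
                raise ConfigError("effect shifts must be finite")


def generate_cohort(config: SyntheticConfig | None = None,
                    panel: MarkerPanel | None = None,
                    seed: int | None = None) -> CtMatrix:
    """Draw one synthetic cohort; bit-identical given the same config+seed."""
    panel = panel or MarkerPanel()
    config = config or SyntheticConfig()
    config.validate(panel)
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)

    base = dict(config.base_ct) if config.base_ct is not None \
        else default_base_ct(panel)
    missing = [m for m in panel.markers if m not in base]
    if missing:
        raise ConfigError(f"base_ct lacks markers: {missing}")

    markers = list(panel.markers)
    groups_order = [g for g in GROUPS if config.group_sizes.get(g, 0) > 0]
    labels, ids = [], []
    for g in groups_order:
        size = int(config.group_sizes[g])
        labels.extend([g] * size)
        ids.extend(f"{g}_{k + 1:03d}" for k in range(size))
    n = len(labels)
    if n == 0:
        raise ConfigError("cohort would be empty")

    ct = np.empty((n, len(markers)))
    for j, m in enumerate(markers):
        ct[:, j] = base[m]
    shift = {(m, g): 0.0 for m in markers for g in GROUPS}
    for marker, group, delta in config.effects:
        shift[(marker, group)] += float(delta)
    for i, g in enumerate(labels):
        for j, m in enumerate(markers):
            ct[i, j] += shift[(m, g)]

    offsets = rng.normal(0.0, config.loading_sd, size=n)
    noise = rng.normal(0.0, config.noise_sd, size=ct.shape)
    ct += offsets[:, None] + noise

    frame = pd.DataFrame(ct, index=pd.Index(ids, name="sample_id"),
                         columns=markers)
    return CtMatrix(frame, pd.Series(labels, index=frame.index, name="group"))


def null_cohort(config: SyntheticConfig | None = None,
                panel: MarkerPanel | None = None,
                seed: int | None = None) -> CtMatrix:
    """A cohort with no group effects (for type-I-error and coverage work)."""
    config = config or SyntheticConfig()
    cfg = SyntheticConfig(group_sizes=dict(config.group_sizes),
                          base_ct=config.base_ct, effects=(),
                          noise_sd=config.noise_sd,
                          loading_sd=config.loading_sd, seed=config.seed)
    return generate_cohort(cfg, panel=panel, seed=seed)
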