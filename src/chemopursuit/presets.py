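"""Named search strategies with their optimized parameter values.

Five strategies are distinguished by which response channels are active
and which of the 7 immune-cell parameters are free during optimization:

* ``bls`` — blind search: no sensing (c_A1 = c_R1 = 0), a strong bias
  for the normal mode (c_A0 = −5, spontaneous approach probability
  ≈ 0.007), hence a homogeneous correlated random walk.  Free: v_N, ε_N;
  optimum (6, 1).
* ``rms`` — random mode switching: still blind, but spontaneous
  switching between the two modes.  Free: v_N, ε_N, v_A, ε_A, c_A0;
  optimization collapses it onto an always-approach ballistic walk.
* ``tgs`` — temporal gradient sensing: the central sensor drives mode
  switching (c_A1 = 500); in rising concentration the cell runs fast and
  straight (approach: v_A = 6, ε_A = 1), in falling concentration it
  tumbles (normal: v_N = 6, ε_N = 0) — a run-and-tumble strategy.
* ``sgs`` — spatial gradient sensing: always in approach mode
  (c_A0 = 500 as an override), steering by the lateral sensors
  (c_R1 = 500) at full speed with persistence 0.8.
* ``cgs`` — combined gradient sensing: spatial steering as in SGS plus
  a temporal channel that drops persistence in strongly falling
  concentration.
"""

from __future__ import annotations

from dataclasses import dataclass

from .response import StrategyParams

__all__ = ["Preset", "PRESETS", "get_preset", "BLS_VARIANTS"]


@dataclass(frozen=True)
class Preset:
    name: str
    params: StrategyParams
    free: tuple[str, ...]  # parameters optimized for this family


PRESETS: dict[str, Preset] = {
    "bls": Preset(
        "bls",
        StrategyParams(v_N=6, eps_N=1, v_A=3, eps_A=0.5, c_A0=-5, c_A1=0, c_R1=0),
        free=("v_N", "eps_N"),
    ),
    "rms": Preset(
        "rms",
        StrategyParams(v_N=4, eps_N=0, v_A=6, eps_A=1, c_A0=5, c_A1=0, c_R1=0),
        free=("v_N", "eps_N", "v_A", "eps_A", "c_A0"),
    ),
    "tgs": Preset(
        "tgs",
        StrategyParams(v_N=6, eps_N=0, v_A=6, eps_A=1, c_A0=2, c_A1=500, c_R1=0),
        free=("v_N", "eps_N", "v_A", "eps_A", "c_A0", "c_A1"),
    ),
    "sgs": Preset(
        "sgs",
        StrategyParams(v_N=3, eps_N=0.5, v_A=6, eps_A=0.8, c_A0=500, c_A1=0, c_R1=500),
        free=("v_A", "eps_A", "c_R1"),
    ),
    "cgs": Preset(
        "cgs",
        StrategyParams(v_N=6, eps_N=0.5, v_A=6, eps_A=0.8, c_A0=5, c_A1=500, c_R1=500),
        free=("v_N", "eps_N", "v_A", "eps_A", "c_A0", "c_A1", "c_R1"),
    ),
}

#: Sub-optimal blind-search parameter points reported alongside the optimum.
BLS_VARIANTS: dict[str, StrategyParams] = {
    "bls_v3_e05": StrategyParams(v_N=3, eps_N=0.5, v_A=3, eps_A=0.5, c_A0=-5, c_A1=0, c_R1=0),
    "bls_v6_e05": StrategyParams(v_N=6, eps_N=0.5, v_A=3, eps_A=0.5, c_A0=-5, c_A1=0, c_R1=0),
    "bls_v6_e1": PRESETS["bls"].params,
}


def get_preset(name: str) -> Preset:
    try:
        return PRESETS[name.lower()]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; choose from {sorted(PRESETS)}"
        ) from None
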