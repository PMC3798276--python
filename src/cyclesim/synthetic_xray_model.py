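"""SYNTHETIC stand-in parameterization of an X-ray response model.

This module encodes a plausible multi-dose radiation-response model for an
exponentially growing ovarian-carcinoma-like cell line, assembled *once*
from published qualitative dose-dependencies of checkpoint activities
(G1/G2M block probabilities and blocked-cell fates per generation, S-phase
delays split by BrdU label in the directly exposed generation, and
polyploidization rates).  It is a synthetic object: the original best-fit
parameter values are not publicly tabulated, so these numbers are anchor
points interpolating the narrative (weak G1 block at 0.5 Gy saturating from
2.5 Gy; G2M interception rising to >95% at 10 Gy with >=95% eventual
recycling in the exposed generation; ~50% G1 interception in descendant
generations at >=2.5 Gy with predominant death/arrest; S delays exceeding a
half rate reduction at high dose; about one third of newborn re-fusions at
10 Gy).

Use for demonstrations, in-silico experiments and integration tests — not
as a source of quantitative biology.
"""

from __future__ import annotations

from .engine import AgeGrid, ModelConfig, igrov1_like_config
from .perturbations import PerturbationSpec

__all__ = ["DOSES_GY", "xray_standin_config"]

DOSES_GY = (0.5, 2.5, 5.0, 10.0)

# per-dose anchors: dose -> value
_G1_PBL_GEN0 = {0.5: 0.20, 2.5: 0.55, 5.0: 0.60, 10.0: 0.60}
_G1_REC_FRAC_GEN0 = {0.5: 1.00, 2.5: 0.60, 5.0: 0.40, 10.0: 0.25}
_G2M_PBL_GEN0 = {0.5: 0.20, 2.5: 0.55, 5.0: 0.85, 10.0: 0.96}
_G1_PBL_DESC = {0.5: 0.25, 2.5: 0.50, 5.0: 0.50, 10.0: 0.50}
_G2M_PBL_DESC = {0.5: 0.10, 2.5: 0.40, 5.0: 0.60, 10.0: 0.80}
_DEL_S_GEN0_POS = {0.5: 0.05, 2.5: 0.15, 5.0: 0.20, 10.0: 0.30}
_DEL_S_GEN0_NEG = {0.5: 0.05, 2.5: 0.20, 5.0: 0.40, 10.0: 0.55}
_DEL_S_GEN1 = {0.5: 0.10, 2.5: 0.50, 5.0: 0.50, 10.0: 0.50}
_P_POL = {0.5: 0.02, 2.5: 0.10, 5.0: 0.17, 10.0: 0.33}


def _g1_gen0_fates(dose: float, scale: float = 0.04) -> tuple[float, float]:
    """Per-step (dr_bl, rec) with the stated eventual recycled fraction."""
    f = _G1_REC_FRAC_GEN0[dose]
    return (1.0 - f) * scale, f * scale


def xray_standin_config(
    dose: float, grid: AgeGrid | None = None, n_cycles: int = 4
) -> ModelConfig:
    """Synthetic stand-in treated-model configuration for one dose (Gy).

    The final cycle pools generations >= n_cycles-1 (default: g3+).
    """
    if dose not in DOSES_GY:
        raise ValueError(f"stand-in defined for doses {DOSES_GY}, got {dose}")
    dr_g1, rec_g1 = _g1_gen0_fates(dose)
    desc = (1, 2) if n_cycles > 3 else (1,)
    # descendant G1 fate: temporary arrest at 0.5 Gy, death/arrest at >= 2.5
    g1_desc_fate = (0.002, 0.04) if dose == 0.5 else (0.02, 0.004)
    # G2M fate in gen1 recycles below 10 Gy; gen2 mostly dies at >= 2.5
    g2m_gen1_fate = (0.005, 0.05) if dose < 10.0 else (0.04, 0.01)
    g2m_gen2_fate = g2m_gen1_fate if dose == 0.5 else (0.03, 0.005)
    perts = [
        PerturbationSpec(
            kind="block_recycle", phase="G1", cycles=(0,),
            params={"p_bl": _G1_PBL_GEN0[dose], "dr_bl": dr_g1, "rec": rec_g1},
        ),
        PerturbationSpec(
            kind="block_recycle", phase="G2M", cycles=(0,),
            params={"p_bl": _G2M_PBL_GEN0[dose], "dr_bl": 0.003, "rec": 0.06},
        ),
        PerturbationSpec(
            kind="block_recycle", phase="G1", cycles=desc,
            params={"p_bl": _G1_PBL_DESC[dose],
                    "dr_bl": g1_desc_fate[0], "rec": g1_desc_fate[1]},
        ),
        PerturbationSpec(
            kind="block_recycle", phase="G2M", cycles=(1,),
            params={"p_bl": _G2M_PBL_DESC[dose],
                    "dr_bl": g2m_gen1_fate[0], "rec": g2m_gen1_fate[1]},
        ),
        PerturbationSpec(
            kind="delay", phase="S", cycles=(0,), label="pos",
            params={"del_ph": _DEL_S_GEN0_POS[dose]},
        ),
        PerturbationSpec(
            kind="delay", phase="S", cycles=(0,), label="neg",
            params={"del_ph": _DEL_S_GEN0_NEG[dose]},
        ),
        PerturbationSpec(
            kind="delay", phase="S", cycles=(1,),
            params={"del_ph": _DEL_S_GEN1[dose]},
        ),
        PerturbationSpec(
            kind="polyploid", cycles=desc,
            params={"p_pol": _P_POL[dose], "dr_pol": 0.001},
        ),
    ]
    if n_cycles > 3:
        perts.append(
            PerturbationSpec(
                kind="block_recycle", phase="G2M", cycles=(2,),
                params={"p_bl": _G2M_PBL_DESC[dose],
                        "dr_bl": g2m_gen2_fate[0], "rec": g2m_gen2_fate[1]},
            )
        )
    return igrov1_like_config(
        grid=grid or AgeGrid(delta_h=0.5),
        n_cycles=n_cycles,
        perturbations=tuple(perts),
    )
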