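"""Destrieux sulco-gyral parcellation bookkeeping.

Regional cortical thickness is summarized per Destrieux region and
hemisphere, in the column dialect written by FreeSurfer's
``aparcstats2table`` (``lh_<region>_thickness`` / ``rh_<region>_thickness``).
This module owns the canonical region-name list and the column-name
round-trip; nothing here touches surfaces or annot files.
"""

from __future__ import annotations

HEMISPHERES = ("left", "right")

_HEMI_PREFIX = {"lh": "left", "rh": "right"}
_PREFIX_HEMI = {v: k for k, v in _HEMI_PREFIX.items()}

# 75 sulco-gyral structures per hemisphere, as counted in regional thickness
# tables for this parcellation.
DESTRIEUX_REGIONS: tuple[str, ...] = (
    "G_and_S_frontomargin",
    "G_and_S_occipital_inf",
    "G_and_S_paracentral",
    "G_and_S_subcentral",
    "G_and_S_transv_frontopol",
    "G_and_S_cingul-Ant",
    "G_and_S_cingul-Mid-Ant",
    "G_and_S_cingul-Mid-Post",
    "G_cingul-Post-dorsal",
    "G_cingul-Post-ventral",
    "G_cuneus",
    "G_front_inf-Opercular",
    "G_front_inf-Orbital",
    "G_front_inf-Triangul",
    "G_front_middle",
    "G_front_sup",
    "G_Ins_lg_and_S_cent_ins",
    "G_insular_short",
    "G_occipital_middle",
    "G_occipital_sup",
    "G_oc-temp_lat-fusifor",
    "G_oc-temp_med-Lingual",
    "G_oc-temp_med-Parahip",
    "G_orbital",
    "G_pariet_inf-Angular",
    "G_pariet_inf-Supramar",
    "G_parietal_sup",
    "G_postcentral",
    "G_precentral",
    "G_precuneus",
    "G_rectus",
    "G_subcallosal",
    "G_temp_sup-G_T_transv",
    "G_temp_sup-Lateral",
    "G_temp_sup-Plan_polar",
    "G_temp_sup-Plan_tempo",
    "G_temporal_inf",
    "G_temporal_middle",
    "Lat_Fis-ant-Horizont",
    "Lat_Fis-ant-Vertical",
    "Lat_Fis-post",
    "Pole_occipital",
    "Pole_temporal",
    "S_calcarine",
    "S_central",
    "S_cingul-Marginalis",
    "S_circular_insula_ant",
    "S_circular_insula_inf",
    "S_circular_insula_sup",
    "S_collat_transv_ant",
    "S_collat_transv_post",
    "S_front_inf",
    "S_front_middle",
    "S_front_sup",
    "S_front_vertical",
    "S_interm_prim-Jensen",
    "S_intrapariet_and_P_trans",
    "S_oc_middle_and_Lunatus",
    "S_oc_sup_and_transversal",
    "S_occipital_ant",
    "S_oc-temp_lat",
    "S_oc-temp_med_and_Lingual",
    "S_orbital_lateral",
    "S_orbital_med-olfact",
    "S_orbital-H_Shaped",
    "S_parieto_occipital",
    "S_pericallosal",
    "S_postcentral",
    "S_precentral-inf-part",
    "S_precentral-sup-part",
    "S_suborbital",
    "S_subparietal",
    "S_temporal_inf",
    "S_temporal_sup",
    "S_temporal_transverse",
)


def thickness_column(hemisphere: str, region: str) -> str:
    """Column name for a (hemisphere, region) pair, aparcstats2table style."""
    if hemisphere not in _PREFIX_HEMI:
        raise ValueError(f"unknown hemisphere {hemisphere!r}; expected 'left' or 'right'")
    return f"{_PREFIX_HEMI[hemisphere]}_{region}_thickness"


def parse_thickness_column(name: str) -> tuple[str, str]:
    """Parse ``lh_<region>_thickness`` into ``(hemisphere, region)``.

    >>> parse_thickness_column("lh_S_circular_insula_ant_thickness")
    ('left', 'S_circular_insula_ant')
    """
    parts = name.split("_", 1)
    if len(parts) != 2 or parts[0] not in _HEMI_PREFIX or not name.endswith("_thickness"):
        raise ValueError(
            f"column {name!r} is not of the form lh_<region>_thickness / rh_<region>_thickness"
        )
    region = parts[1][: -len("_thickness")]
    if not region:
        raise ValueError(f"column {name!r} has an empty region name")
    return _HEMI_PREFIX[parts[0]], region
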