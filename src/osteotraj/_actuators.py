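"""The 38-actuator topology of the idealized hindlimb.

34 musculotendon actuators plus the four collateral (knee/ankle)
ligaments, with origins, via points and insertions placed on the
synthetic bones at reduced anatomical fidelity: attachment sites sit
near the centroid of the real attachment areas of the avian homologues,
and via points are the minimum needed for realistic lines of action
(plantarflexors deflected behind the ankle, dorsiflexors in front,
digital flexors under the metatarsophalangeal joint).

Every actuator defaults to f_max = 2 BW; ``TABLE_FMAX`` holds the
muscle-specific maximum forces (N, junglefowl-scaled, isometric stress
3e5 N/m^2) used by the muscle-force sensitivity mode.  ``ACTIVE`` flags
which muscles exert force in a mid-stance simulation; ligaments are
always included as passive linear reserves.
"""

from __future__ import annotations

import numpy as np

from .statics import Actuator

#: mid-stance activity flags (X = True)
ACTIVE = {
    "IC": False, "ILPR": False, "ILPO": True, "AMB": True, "FMTE": True,
    "FMTM": True, "FMTI": True, "ILFB": True, "FCLP": True, "FCLA": True,
    "FCM": True, "IFE": False, "IFI": False, "ITCR": False, "ITM": True,
    "ITC": True, "ISF": True, "CFC": True, "CFP": True, "OM": False,
    "PIFL": True, "PIFM": True, "GL": True, "GI": True, "GM": True,
    "FDL": True, "ODF": True, "FHL": True, "EDL": False, "ODE": False,
    "TCF": False, "TCT": False, "FL": True, "FB": True,
    "KMCL": True, "KLCL": True, "AMCL": True, "ALCL": True,
}

#: muscle-specific maximum forces for the sensitivity mode (N)
TABLE_FMAX = {
    "ILPO": 30.111, "AMB": 1.112, "FMTE": 19.636, "FMTM": 21.007,
    "FMTI": 92.110, "ILFB": 24.777, "FCLP": 20.760, "FCLA": 18.656,
    "FCM": 8.713, "ITM": 3.003, "ITC": 77.382, "ISF": 25.635,
    "CFC": 1.625, "CFP": 6.300, "PIFL": 7.981, "PIFM": 17.940,
    "GL": 59.539, "GI": 10.863, "GM": 71.969, "FDL": 31.022,
    "ODF": 58.122, "FHL": 22.672, "FL": 51.621, "FB": 8.737,
}


def _sites(model):
    """Attachment-site coordinates in segment-local frames."""
    p = model.params
    d = p.head_offset
    pelvis = {
        "dorsal_crest_ant": (0.035, -0.002, 0.030),
        "dl_crest_ant": (0.020, -0.008, 0.028),
        "dl_crest_post": (-0.028, -0.008, 0.028),
        "pubis_preacet": (0.012, -0.004, -0.008),
        "postacet_ilium": (-0.028, -0.010, 0.020),
        "post_ilium_caud": (-0.052, -0.008, 0.015),
        "post_ischium": (-0.048, 0.002, -0.006),
        "vent_preacet_itcr": (0.015, -0.009, 0.008),
        "vent_preacet_itm": (0.010, -0.009, 0.008),
        "lat_preacet": (0.018, -0.010, 0.015),
        "vent_preacet_ifi": (0.012, -0.006, 0.004),
        "supratroch": (0.002, -0.010, 0.012),
        "lat_ischium": (-0.026, -0.008, -0.004),
        "pygostyle": (-0.062, -0.002, 0.010),
        "lat_ilium_cfp": (-0.036, -0.009, 0.016),
        "med_ischiopubis": (-0.015, 0.004, -0.010),
        "vent_ischiopubis_l": (-0.009, 0.004, -0.016),
        "vent_ischiopubis_m": (-0.008, 0.008, -0.018),
    }
    Lf = p.femur_length
    femur = {
        "troch_ant_lat": (0.004, -d - 0.005, -0.010),
        "troch_shelf": (0.001, -d - 0.005, -0.013),
        "troch_cr": (0.0045, -d - 0.004, -0.008),
        "med_prox": (0.000, -d + 0.004, -0.016),
        "lat_prox": (0.000, -d - 0.0045, -0.016),
        "post_prox_cfc": (-0.005, -d - 0.001, -0.020),
        "post_prox_cfp": (-0.005, -d - 0.003, -0.020),
        "postlat_prox": (-0.004, -d - 0.003, -0.017),
        "ant_shaft": (0.0045, -d, -0.040),
        "lat_shaft": (0.000, -d - 0.0045, -0.040),
        "med_shaft": (0.000, -d + 0.0045, -0.040),
        "post_shaft_l": (-0.0045, -d - 0.002, -0.045),
        "post_shaft_m": (-0.0045, -d + 0.003, -0.054),
        "dist_post": (-0.006, -d, -Lf + 0.009),
        "lat_condyle": (0.000, -d - 0.009, -Lf + 0.007),
        "lat_condyle_prox": (0.002, -d - 0.007, -Lf + 0.009),
        "med_condyle": (0.000, -d + 0.009, -Lf + 0.007),
        "med_condyle_prox": (0.002, -d + 0.007, -Lf + 0.009),
        "popliteal": (-0.007, -d, -Lf + 0.006),
        "dist_lat_tcf": (0.003, -d - 0.007, -Lf + 0.005),
        "patellar": (0.012, -d, -Lf + 0.001),
    }
    Lt = p.tibiotarsus_length
    tib = {
        "ant_cnem": (0.014, 0.000, -0.012),
        "ant_cnem_med": (0.012, 0.003, -0.011),
        "ant_cnem_dist": (0.010, 0.000, -0.022),
        "lat_cnem": (0.007, -0.008, -0.009),
        "fib_head_lat": (0.000, -0.0095, -0.009),
        "fib_tubercle": (-0.002, -0.0095, -0.016),
        "med_prox": (0.000, 0.0065, -0.013),
        "med_prox_fcm": (0.000, 0.0060, -0.024),
        "med_prox_lig": (0.000, 0.0065, -0.009),
        "ant_shaft": (0.0048, 0.000, -0.035),
        "antlat_shaft": (0.004, -0.006, -0.028),
        "caud_shaft": (-0.0048, 0.000, -0.045),
        "antmed_prox_gm": (0.0045, 0.004, -0.015),
        "post_prox_gastroc": (-0.007, 0.000, -0.006),
        "med_condyle_lig": (0.000, 0.0062, -Lt + 0.008),
        "lat_condyle_lig": (0.000, -0.0062, -Lt + 0.008),
        "post_ankle": (-0.012, 0.000, -Lt + 0.0055),
        "ant_ankle": (0.0050, 0.000, -Lt + 0.006),
    }
    Lm = p.tarsometatarsus_length
    tmt = {
        "ant_prox": (0.0042, 0.000, -0.008),
        "post_prox": (-0.016, 0.000, -0.012),
        "hypotarsus": (-0.013, 0.000, -0.004),
        "post_shaft": (-0.0042, 0.000, -0.035),
        "ant_shaft": (0.0042, 0.000, -0.038),
        "lat_prox": (0.000, -0.0050, -0.008),
        "lat_prox_ant": (0.002, -0.0048, -0.007),
        "med_prox": (0.000, 0.0050, -0.008),
        "post_dist": (-0.0058, 0.000, -Lm + 0.006),
        "ant_dist": (0.0040, 0.000, -Lm + 0.008),
    }
    pes = {
        "vent_mid": (0.020, 0.000, -p.pes_height),
        "vent_dist": (0.030, 0.000, -p.pes_height),
        "dors_mid": (0.020, 0.000, 0.000),
        "vent_prox": (0.008, 0.000, -p.pes_height),
    }
    return {"pelvis": pelvis, "thigh": femur, "shank": tib, "tarsometatarsus": tmt, "pes": pes}


#: (name, kind, [(segment, site), ...]) origin -> insertion
_TOPOLOGY = [
    ("IC", "muscle", [("pelvis", "dorsal_crest_ant"), ("thigh", "patellar"), ("shank", "ant_cnem_med")]),
    ("ILPR", "muscle", [("pelvis", "dl_crest_ant"), ("thigh", "patellar"), ("shank", "ant_cnem")]),
    ("ILPO", "muscle", [("pelvis", "dl_crest_post"), ("thigh", "patellar"), ("shank", "ant_cnem")]),
    ("AMB", "muscle", [("pelvis", "pubis_preacet"), ("shank", "fib_head_lat")]),
    ("FMTE", "muscle", [("thigh", "lat_shaft"), ("thigh", "patellar"), ("shank", "ant_cnem")]),
    ("FMTM", "muscle", [("thigh", "ant_shaft"), ("thigh", "patellar"), ("shank", "ant_cnem")]),
    ("FMTI", "muscle", [("thigh", "med_shaft"), ("thigh", "patellar"), ("shank", "ant_cnem_med")]),
    ("ILFB", "muscle", [("pelvis", "postacet_ilium"), ("shank", "fib_tubercle")]),
    ("FCLP", "muscle", [("pelvis", "post_ilium_caud"), ("shank", "med_prox")]),
    ("FCLA", "muscle", [("pelvis", "post_ilium_caud"), ("thigh", "dist_post")]),
    ("FCM", "muscle", [("pelvis", "post_ischium"), ("shank", "med_prox_fcm")]),
    ("IFE", "muscle", [("pelvis", "supratroch"), ("thigh", "troch_shelf")]),
    ("IFI", "muscle", [("pelvis", "vent_preacet_ifi"), ("thigh", "med_prox")]),
    ("ITCR", "muscle", [("pelvis", "vent_preacet_itcr"), ("thigh", "troch_ant_lat")]),
    ("ITM", "muscle", [("pelvis", "vent_preacet_itm"), ("thigh", "troch_ant_lat")]),
    ("ITC", "muscle", [("pelvis", "lat_preacet"), ("thigh", "troch_cr")]),
    ("ISF", "muscle", [("pelvis", "lat_ischium"), ("thigh", "lat_prox")]),
    ("CFC", "muscle", [("pelvis", "pygostyle"), ("thigh", "post_prox_cfc")]),
    ("CFP", "muscle", [("pelvis", "lat_ilium_cfp"), ("thigh", "post_prox_cfp")]),
    ("OM", "muscle", [("pelvis", "med_ischiopubis"), ("thigh", "postlat_prox")]),
    ("PIFL", "muscle", [("pelvis", "vent_ischiopubis_l"), ("thigh", "post_shaft_l")]),
    ("PIFM", "muscle", [("pelvis", "vent_ischiopubis_m"), ("thigh", "post_shaft_m")]),
    ("GL", "muscle", [("thigh", "lat_condyle_prox"), ("shank", "post_prox_gastroc"), ("shank", "post_ankle"), ("tarsometatarsus", "hypotarsus"), ("tarsometatarsus", "post_prox")]),
    ("GI", "muscle", [("thigh", "med_condyle_prox"), ("shank", "post_prox_gastroc"), ("shank", "post_ankle"), ("tarsometatarsus", "hypotarsus"), ("tarsometatarsus", "post_prox")]),
    ("GM", "muscle", [("shank", "antmed_prox_gm"), ("shank", "post_ankle"), ("tarsometatarsus", "hypotarsus"), ("tarsometatarsus", "post_prox")]),
    ("FDL", "muscle", [("shank", "caud_shaft"), ("shank", "post_ankle"), ("tarsometatarsus", "hypotarsus"), ("tarsometatarsus", "post_prox"), ("tarsometatarsus", "post_dist"), ("pes", "vent_mid")]),
    ("ODF", "muscle", [("thigh", "popliteal"), ("shank", "post_ankle"), ("tarsometatarsus", "hypotarsus"), ("tarsometatarsus", "post_prox"), ("tarsometatarsus", "post_dist"), ("pes", "vent_mid")]),
    ("FHL", "muscle", [("thigh", "popliteal"), ("shank", "post_ankle"), ("tarsometatarsus", "hypotarsus"), ("tarsometatarsus", "post_prox"), ("tarsometatarsus", "post_dist"), ("pes", "vent_dist")]),
    ("EDL", "muscle", [("shank", "ant_shaft"), ("shank", "ant_ankle"), ("tarsometatarsus", "ant_dist"), ("pes", "dors_mid")]),
    ("ODE", "muscle", [("tarsometatarsus", "ant_shaft"), ("pes", "dors_mid")]),
    ("TCF", "muscle", [("thigh", "dist_lat_tcf"), ("shank", "ant_ankle"), ("tarsometatarsus", "ant_prox")]),
    ("TCT", "muscle", [("shank", "ant_cnem_dist"), ("shank", "ant_ankle"), ("tarsometatarsus", "ant_prox")]),
    ("FL", "muscle", [("shank", "lat_cnem"), ("shank", "post_ankle"), ("tarsometatarsus", "hypotarsus"), ("tarsometatarsus", "post_prox"), ("tarsometatarsus", "post_dist"), ("pes", "vent_mid")]),
    ("FB", "muscle", [("shank", "antlat_shaft"), ("tarsometatarsus", "lat_prox")]),
    ("KMCL", "ligament", [("thigh", "med_condyle"), ("shank", "med_prox_lig")]),
    ("KLCL", "ligament", [("thigh", "lat_condyle"), ("shank", "fib_head_lat")]),
    ("AMCL", "ligament", [("shank", "med_condyle_lig"), ("tarsometatarsus", "med_prox")]),
    ("ALCL", "ligament", [("shank", "lat_condyle_lig"), ("tarsometatarsus", "lat_prox_ant")]),
]


def build_actuators(model, f_max_mode: str = "uniform") -> list[Actuator]:
    """Build the actuator set.

    ``uniform``: every actuator gets f_max = 2 BW.  ``per_muscle``:
    active muscles get their architecture-specific values
    (``TABLE_FMAX``); ligaments keep 2 BW.
    """
    sites = _sites(model)
    default_fmax = 2.0 * model.body_weight
    out = []
    for name, kind, path_spec in _TOPOLOGY:
        path = [(seg, np.array(sites[seg][site], float)) for seg, site in path_spec]
        fmax = default_fmax
        if f_max_mode == "per_muscle" and name in TABLE_FMAX:
            fmax = TABLE_FMAX[name]
        out.append(Actuator(name=name, kind=kind, path=path, active=ACTIVE[name], f_max=fmax))
    return out


def set_f_max_mode(model, mode: str) -> None:
    """Switch the model's actuators between uniform 2 BW and per-muscle
    maximum forces (the sensitivity mode); identical solver path."""
    model.actuators = build_actuators(model, f_max_mode=mode)
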