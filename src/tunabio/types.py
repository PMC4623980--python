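"""Shared vocabulary for Atlantic bluefin tuna biometrics.

Two management stocks (East Atlantic including the Mediterranean, and West
Atlantic, split at 45°W), five length measurement types, five weight
measurement types, and fourteen sampling areas grouped into the broad
regions used by the seasonal condition analysis.
"""

from __future__ import annotations

import enum


class Stock(str, enum.Enum):
    """Management unit: Eastern (incl. Mediterranean) or Western Atlantic."""

    EAST = "EAST"
    WEST = "WEST"


class Measurement(str, enum.Enum):
    """Length (cm) and weight (kg) measurement types recorded in the field."""

    # lengths, cm
    SFL = "SFL"        # straight fork length (standard length unit)
    CFL = "CFL"        # curved fork length, over the body curvature
    LD1 = "LD1"        # snout to first dorsal spine
    HEADL = "HeadL"    # snout to posterior border of operculum
    PREOPL = "PreopL"  # snout to posterior border of preoperculum
    # weights, kg
    RWT = "RWT"        # round (whole) weight -- standard weight unit
    GWT = "GWT"        # gutted weight
    GGWT = "GGWT"      # gutted and gilled
    GGTWT = "GGTWT"    # gutted, gilled and tailed
    DWT = "DWT"        # dressed: gutted, head off, tail off

    @property
    def is_length(self) -> bool:
        return self in LENGTH_TYPES

    @property
    def is_weight(self) -> bool:
        return self in WEIGHT_TYPES


LENGTH_TYPES = frozenset(
    {Measurement.SFL, Measurement.CFL, Measurement.LD1,
     Measurement.HEADL, Measurement.PREOPL}
)
WEIGHT_TYPES = frozenset(
    {Measurement.RWT, Measurement.GWT, Measurement.GGWT,
     Measurement.GGTWT, Measurement.DWT}
)

#: DataFrame / CSV column used for each raw measurement type.
COLUMN_FOR: dict[Measurement, str] = {
    Measurement.SFL: "sfl_cm",
    Measurement.CFL: "cfl_cm",
    Measurement.LD1: "ld1_cm",
    Measurement.HEADL: "headl_cm",
    Measurement.PREOPL: "preopl_cm",
    Measurement.RWT: "rwt_kg",
    Measurement.GWT: "gwt_kg",
    Measurement.GGWT: "ggwt_kg",
    Measurement.GGTWT: "ggtwt_kg",
    Measurement.DWT: "dwt_kg",
}

#: Public schema of a fish-record table (one row per sampled fish).
RECORD_COLUMNS: list[str] = [
    "fish_id", "stock", "area", "gear", "year", "month",
    *COLUMN_FOR.values(),
]

#: Latent-truth companion columns carried by synthetic records for oracles.
LATENT_COLUMNS: list[str] = ["age", "sfl_true", "rwt_true"]


class Area(str, enum.Enum):
    """Geographic sampling areas (WATL = unidentified western Atlantic)."""

    GOM = "GOM"          # Gulf of Mexico
    SABFEC = "SABFEC"    # South Atlantic bight / Florida East Coast / Sargasso
    MAB = "MAB"          # Mid-Atlantic Bight
    MAGESS = "MAGESS"    # Gulf of Maine, George's Bank, Scotian Shelf
    GSL = "GSL"          # Gulf of St. Lawrence
    WCA = "WCA"          # Western Central Atlantic
    WATL = "WATL"        # unidentified western Atlantic
    ECA = "ECA"          # Eastern Central Atlantic
    BB = "BB"            # Bay of Biscay
    AIMA = "AIMA"        # Atlantic Iberian-Moroccan Area
    SG = "SG"            # Strait of Gibraltar
    WM = "WM"            # Western Mediterranean
    CM = "CM"            # Central Mediterranean
    EM = "EM"            # Eastern Mediterranean


class AreaGroup(str, enum.Enum):
    """Broad regions used as fixed factors in the condition model."""

    EAST_ATLANTIC = "EAST_ATLANTIC"
    WC_MED = "WC_MED"      # western-central Mediterranean incl. Gibraltar
    E_MED = "E_MED"
    WEST_ATLANTIC = "WEST_ATLANTIC"


#: Area -> condition-analysis region.  The Strait of Gibraltar is grouped
#: with the western-central Mediterranean; all western areas form one group
#: (the Gulf of Mexico is not modelled as a separate factor level).
AREA_GROUP: dict[str, str] = {
    Area.BB.value: AreaGroup.EAST_ATLANTIC.value,
    Area.AIMA.value: AreaGroup.EAST_ATLANTIC.value,
    Area.ECA.value: AreaGroup.EAST_ATLANTIC.value,
    Area.SG.value: AreaGroup.WC_MED.value,
    Area.WM.value: AreaGroup.WC_MED.value,
    Area.CM.value: AreaGroup.WC_MED.value,
    Area.EM.value: AreaGroup.E_MED.value,
    Area.GOM.value: AreaGroup.WEST_ATLANTIC.value,
    Area.SABFEC.value: AreaGroup.WEST_ATLANTIC.value,
    Area.MAB.value: AreaGroup.WEST_ATLANTIC.value,
    Area.MAGESS.value: AreaGroup.WEST_ATLANTIC.value,
    Area.GSL.value: AreaGroup.WEST_ATLANTIC.value,
    Area.WCA.value: AreaGroup.WEST_ATLANTIC.value,
    Area.WATL.value: AreaGroup.WEST_ATLANTIC.value,
}


class Maturity(str, enum.Enum):
    IMMATURE = "IMMATURE"
    MATURE = "MATURE"


#: Size at 100% maturity by stock (SFL, cm); fish at or above are MATURE.
MATURITY_THRESHOLD_CM: dict[Stock, float] = {
    Stock.EAST: 130.0,
    Stock.WEST: 185.0,
}
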