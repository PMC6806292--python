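"""Model parameters for the composite glucose-insulin model.

The parameter set combines the Bergman minimal model of glucose disappearance
with Hovorka's two-compartment subcutaneous insulin and gut absorption chains.
Population constants follow the values commonly used for this composite model;
``si``, ``tmax_i`` and ``tmax_g`` are the subject-specific parameters meant to
be identified from data (see :mod:`glucast.identification`).

Unit conventions
----------------
Glucose is carried in mg/dL, insulin doses in mU (1 U = 1000 mU), plasma
insulin in uU/mL, carbohydrate in mg.  With ``S2`` in mU, ``Vi`` in mL/kg and
``W`` in kg, the insulin appearance term ``S2/(Vi*W*tmaxI)`` is in mU/mL/min;
the single conversion constant :data:`UU_PER_ML_PER_MU_PER_ML` (x1000) brings
it to uU/mL/min so that plasma insulin is in the units insulin sensitivity
expects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np

#: mU per insulin unit (doses are logged in U, the model works in mU).
MU_PER_UNIT = 1000.0
#: mg per gram of carbohydrate.
MG_PER_GRAM = 1000.0
#: conversion of the insulin appearance term from mU/mL/min to uU/mL/min.
UU_PER_ML_PER_MU_PER_ML = 1000.0

#: admissible boxes for the identified parameters
SI_BOUNDS = (0.001, 0.005)
TMAXI_BOUNDS = (50.0, 140.0)
TMAXG_BOUNDS = (50.0, 140.0)

# index layout of the parameter vector consumed by the numeric kernels
IDX_SG, IDX_SI, IDX_GB, IDX_V, IDX_VI, IDX_W, IDX_KE, IDX_P2, IDX_AG = range(9)


@dataclass
class PatientParameters:
    """Constants of the composite model for one subject.

    Attributes
    ----------
    sg : float
        Fractional glucose effectiveness, 1/min.
    si : float
        Insulin sensitivity, 1/min per uU/mL.  Identified per subject.
    gb : float
        Basal glucose, mg/dL.  A-priori known per subject.
    v : float
        Glucose distribution volume, dL/kg.
    vi : float
        Insulin distribution volume, mL/kg.
    w : float
        Body weight, kg.  A-priori known per subject.
    tmax_i : float
        Time to maximum subcutaneous insulin absorption, min.  Identified.
    tmax_g : float
        Time to maximum glucose rate of appearance, min.  Identified.
    ke : float
        Plasma insulin decay rate, 1/min.
    p2 : float
        Insulin action rate, 1/min.
    ag : float
        Carbohydrate bioavailability, dimensionless in (0, 1].
    tl, td : float
        Shifts (min) applied to ``tmax_g`` for fast / slow absorption meals.
    """

    sg: float = 0.02
    si: float = 0.003
    gb: float = 120.0
    v: float = 0.9
    vi: float = 1.2
    w: float = 70.0
    tmax_i: float = 80.0
    tmax_g: float = 70.0
    ke: float = 1.5
    p2: float = 0.02
    ag: float = 0.85
    tl: float = 20.0
    td: float = 20.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for f in fields(self):
            val = getattr(self, f.name)
            if not math.isfinite(val):
                raise ValueError(f"parameter {f.name} is not finite: {val!r}")
        positive = ("sg", "si", "gb", "v", "vi", "w", "tmax_i", "tmax_g", "ke", "p2", "ag")
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name} must be strictly positive")
        if not SI_BOUNDS[0] <= self.si <= SI_BOUNDS[1]:
            raise ValueError(f"si={self.si} outside admissible box {SI_BOUNDS}")
        if not TMAXI_BOUNDS[0] <= self.tmax_i <= TMAXI_BOUNDS[1]:
            raise ValueError(f"tmax_i={self.tmax_i} outside admissible box {TMAXI_BOUNDS}")
        if not TMAXG_BOUNDS[0] <= self.tmax_g <= TMAXG_BOUNDS[1]:
            raise ValueError(f"tmax_g={self.tmax_g} outside admissible box {TMAXG_BOUNDS}")
        if not 0 < self.ag <= 1:
            raise ValueError(f"ag={self.ag} outside (0, 1]")
        if self.tl >= self.tmax_g:
            raise ValueError("tl must be smaller than tmax_g (effective tmax_g > 0)")

    def to_vector(self) -> np.ndarray:
        """Pack the rate/volume constants in the kernel's index layout."""
        return np.array(
            [self.sg, self.si, self.gb, self.v, self.vi, self.w, self.ke, self.p2, self.ag],
            dtype=np.float64,
        )

    def replace(self, **kwargs) -> "PatientParameters":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    @classmethod
    def from_dict(cls, mapping: dict) -> "PatientParameters":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown parameter names: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in mapping.items()})
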