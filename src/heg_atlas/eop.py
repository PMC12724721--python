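"""Plaque-assay titres and efficiency of plaquing (EOP).

EOP is the phage titre on a test host divided by the titre on the permissive
control host; a host expressing an active homing endonuclease against the
incoming phage shows an EOP orders of magnitude below 1.  Titres come from
dilution-series plate counts, using only plates in the standard countable
range and weighting by plaque count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .io import PlaqueCount

#: standard countable plate range (plaques per plate), inclusive
COUNTABLE_RANGE = (3, 300)


@dataclass(frozen=True)
class EOPRecord:
    phage_label: str
    host_label: str
    control_host_label: str
    test_titre: float          # PFU per ml
    control_titre: float
    eop: float
    fold_reduction: float


def titre_from_counts(
    counts: Sequence[PlaqueCount], countable_range: tuple[int, int] = COUNTABLE_RANGE
) -> float:
    """Titre (PFU/ml) from a dilution series of plate counts.

    titre_i = plaques / (plated_volume_ml * 10^dilution_exponent) per
    countable plate, combined as a plaque-count-weighted mean (plates with
    more plaques carry proportionally more information).
    """
    if not counts:
        raise ValueError("no plaque counts supplied")
    exponents = [c.dilution_exponent for c in counts]
    if len(set(exponents)) != len(exponents):
        raise ValueError("dilution series exponents must be distinct per assay")
    lo, hi = countable_range
    countable = [c for c in counts if lo <= c.plaques <= hi]
    if not countable:
        raise ValueError(
            f"no dilution in the countable range [{lo}, {hi}]; "
            "plate further dilutions"
        )
    titres = [
        c.plaques / (c.plated_volume_ml * 10.0 ** c.dilution_exponent) for c in countable
    ]
    weights = [c.plaques for c in countable]
    return sum(w * t for w, t in zip(weights, titres)) / sum(weights)


def efficiency_of_plaquing(
    test_titre: float | Sequence[float],
    control_titre: float | Sequence[float],
    phage_label: str = "",
    host_label: str = "",
    control_host_label: str = "",
    replicate_mean: str = "geometric",
) -> EOPRecord:
    """EOP = test titre / control titre (with 1/EOP as fold reduction).

    When replicate titres are supplied, per-replicate EOPs are reduced by
    geometric mean (EOP is a ratio), or arithmetic mean on request.
    """
    tests = [test_titre] if isinstance(test_titre, (int, float)) else list(test_titre)
    controls = (
        [control_titre] if isinstance(control_titre, (int, float)) else list(control_titre)
    )
    if any(t <= 0 for t in tests) or any(c <= 0 for c in controls):
        raise ValueError("titres must be positive")
    if len(tests) != len(controls):
        raise ValueError("replicate lists must have equal length")
    eops = [t / c for t, c in zip(tests, controls)]
    if replicate_mean == "geometric":
        eop = math.exp(sum(math.log(e) for e in eops) / len(eops))
    elif replicate_mean == "arithmetic":
        eop = sum(eops) / len(eops)
    else:
        raise ValueError("replicate_mean must be 'geometric' or 'arithmetic'")
    return EOPRecord(
        phage_label=phage_label,
        host_label=host_label,
        control_host_label=control_host_label,
        test_titre=sum(tests) / len(tests),
        control_titre=sum(controls) / len(controls),
        eop=eop,
        fold_reduction=1.0 / eop,
    )


def eop_from_counts(
    test_counts: Sequence[PlaqueCount],
    control_counts: Sequence[PlaqueCount],
    **kwargs,
) -> EOPRecord:
    """Convenience: titres from both dilution series, then the EOP."""
    test = titre_from_counts(test_counts)
    control = titre_from_counts(control_counts)
    host = test_counts[0].host_label if test_counts else ""
    chost = control_counts[0].host_label if control_counts else ""
    phage = test_counts[0].phage_label if test_counts else ""
    return efficiency_of_plaquing(
        test, control, phage_label=phage, host_label=host, control_host_label=chost, **kwargs
    )
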