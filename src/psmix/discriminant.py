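"""Linear discriminant scoring of PSM records.

A database search returns several quantities per match (for SEQUEST:
XCorr, deltaCn, SpRank; for a dot-product engine: logDot, deltaDot). A
per-charge linear discriminant collapses them into one summarized score

    S = beta0 + sum_j beta_j * feature_j

trained so that S > 0 for correct matches and S < 0 for incorrect ones.
The coefficients shipped in DEFAULT_COEFFICIENTS are illustrative
placeholders only — real use requires coefficients trained on a
controlled mixture for the engine at hand, or the adaptive module which
re-estimates them from the data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

from psmix.psm_data import PSMRecord, PSMTable

__all__ = [
    "DiscriminantCoefficients",
    "DEFAULT_COEFFICIENTS",
    "apply_discriminant",
    "score_record",
    "read_coefficients",
    "write_coefficients",
]


@dataclass
class DiscriminantCoefficients:
    """Intercept and feature weights of one per-charge linear discriminant."""

    engine: str  # "sequest", "tandem" or "custom"
    charge: int
    intercept: float
    weights: dict[str, float]

    def __post_init__(self) -> None:
        if not self.weights:
            raise ValueError("weights must be non-empty")


#: Illustrative placeholder coefficients; NOT trained values. Real analyses
#: must supply engine-specific coefficients or use the adaptive module.
DEFAULT_COEFFICIENTS: dict[tuple[str, int], DiscriminantCoefficients] = {
    ("sequest", c): DiscriminantCoefficients(
        engine="sequest",
        charge=c,
        intercept=-4.0,
        weights={"XCorr": 8.0, "deltaCn": 7.0, "SpRank": -0.2},
    )
    for c in (1, 2, 3)
} | {
    ("tandem", c): DiscriminantCoefficients(
        engine="tandem",
        charge=c,
        intercept=-5.0,
        weights={"logDot": 1.5, "deltaDot": 4.0},
    )
    for c in (1, 2, 3)
}


def score_record(
    record: PSMRecord,
    coeffs: DiscriminantCoefficients,
    transforms: Mapping[str, Callable[[float], float]] | None = None,
) -> float:
    """Evaluate the discriminant for one record.

    ``transforms`` optionally maps a feature name to a scalar transform
    applied before weighting (default identity).
    """
    score = coeffs.intercept
    for name, weight in coeffs.weights.items():
        if name not in record.features:
            raise KeyError(
                f"record {record.spectrum_id!r} lacks feature {name!r} "
                f"required by the charge-{coeffs.charge} discriminant"
            )
        value = record.features[name]
        if transforms and name in transforms:
            value = transforms[name](value)
        score += weight * value
    return score


def apply_discriminant(
    table: PSMTable,
    coeffs: Mapping[int, DiscriminantCoefficients],
    fallback: DiscriminantCoefficients | None = None,
    transforms: Mapping[str, Callable[[float], float]] | None = None,
) -> PSMTable:
    """Assign a discriminant score to every record (returns a new table).

    ``coeffs`` maps charge to coefficient sets; ``fallback`` covers charges
    without an entry. Records are otherwise unchanged.
    """
    new_records = []
    for rec in table.records:
        cset = coeffs.get(rec.charge, fallback)
        if cset is None:
            raise ValueError(
                f"no discriminant coefficients for charge {rec.charge} and no fallback configured"
            )
        new_records.append(
            PSMRecord(
                spectrum_id=rec.spectrum_id,
                charge=rec.charge,
                features=dict(rec.features),
                discriminant_score=score_record(rec, cset, transforms),
                ntt=rec.ntt,
                nmc=rec.nmc,
                delta_mass=rec.delta_mass,
                is_decoy=rec.is_decoy,
                peptide=rec.peptide,
                protein=rec.protein,
                rank=rec.rank,
                true_label=rec.true_label,
            )
        )
    return PSMTable(records=new_records, metadata=dict(table.metadata))


def read_coefficients(path) -> dict[tuple[str, int], DiscriminantCoefficients]:
    """Read coefficient sets from a plain-text key-value file.

    Format: one line per coefficient set,
    ``engine<TAB>charge<TAB>intercept<TAB>name=value,name=value,...``;
    lines starting with ``#`` are comments.
    """
    out: dict[tuple[str, int], DiscriminantCoefficients] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            engine, charge_s, intercept_s, weights_s = line.split("\t")
            weights = {}
            for item in weights_s.split(","):
                name, value = item.split("=")
                weights[name.strip()] = float(value)
            key = (engine, int(charge_s))
            out[key] = DiscriminantCoefficients(
                engine=engine, charge=int(charge_s), intercept=float(intercept_s), weights=weights
            )
    return out


def write_coefficients(coeffs: Mapping[tuple[str, int], DiscriminantCoefficients], path) -> None:
    """Write coefficient sets in the format of :func:`read_coefficients`."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# engine\tcharge\tintercept\tweights (name=value,...)\n")
        for (engine, charge), cset in sorted(coeffs.items()):
            weights_s = ",".join(f"{k}={repr(v)}" for k, v in cset.weights.items())
            fh.write(f"{engine}\t{charge}\t{repr(cset.intercept)}\t{weights_s}\n")
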