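"""Orthogonal-array composite designs (OACD) for combinatorial drug screens.

An OACD concatenates a two-level fractional-factorial portion (factors at
{absent, high} = coded 0/2) with a three-level orthogonal array (coded
0/1/2), giving enough distinct dose-level profiles to identify a full
second-order response-surface model in far fewer runs than a 3^k factorial.
For the canonical 12-drug panel this yields 128 + 27 = 155 test points
against 91 model coefficients.

Coded levels map to normalized regression doses 0 -> 0.0, 1 -> 0.5,
2 -> 1.0; :func:`map_levels_to_doses` maps them to molar concentrations of
a :class:`DrugPanel`.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "DesignUnavailableError",
    "DoseCapError",
    "DrugPanel",
    "DesignMatrix",
    "build_two_level_fraction",
    "build_three_level_oa",
    "generate_oacd",
    "map_levels_to_doses",
    "min_defining_word_length",
    "load_panel",
    "write_design",
    "read_design",
]

#: coded level -> numeric regression input (normalized dose)
NUMERIC_CODE: Mapping[int, float] = {0: 0.0, 1: 0.5, 2: 1.0}

TWO_LEVEL = "two_level"
THREE_LEVEL = "three_level"


class DesignUnavailableError(ValueError):
    """No stored construction exists for the requested factor count."""


class DoseCapError(ValueError):
    """A tested concentration violates the panel's dose cap."""


# ---------------------------------------------------------------------------
# drug panel
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DrugPanel:
    """An ordered drug panel with three tested concentrations per drug.

    Parameters
    ----------
    drugs : sequence of str
        Drug identifiers; order fixes the design-column order.
    doses : sequence of (float, float, float)
        Per drug, the concentrations (molar) for coded levels 0/1/2.
        Level 0 is always 0 (drug absent) and doses are strictly increasing.
    cmax : mapping, optional
        Maximum serum concentration (molar) per drug.  When present, the
        top tested dose must not exceed 10% of it.
    ic10 : mapping, optional
        IC10 concentration (molar) per drug; also caps the top dose.
    """

    drugs: tuple[str, ...]
    doses: tuple[tuple[float, float, float], ...]
    cmax: Mapping[str, float] = field(default_factory=dict)
    ic10: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "drugs", tuple(self.drugs))
        object.__setattr__(self, "doses", tuple(tuple(d) for d in self.doses))
        if len(self.drugs) < 2:
            raise ValueError("panel needs at least 2 drugs")
        if len(set(self.drugs)) != len(self.drugs):
            raise ValueError("duplicate drug names in panel")
        if len(self.doses) != len(self.drugs):
            raise ValueError("doses must be given for every drug")
        for name, (d0, d1, d2) in zip(self.drugs, self.doses):
            if d0 != 0.0:
                raise ValueError(f"{name}: level-0 dose must be 0 (drug absent)")
            if not (d0 < d1 < d2):
                raise ValueError(f"{name}: doses must be strictly increasing")
            cap = self.dose_cap(name)
            if cap is not None and d2 > cap * (1 + 1e-12):
                raise DoseCapError(
                    f"{name}: top dose {d2:g} M exceeds cap {cap:g} M "
                    "(min of 10% Cmax and IC10)"
                )

    @property
    def k(self) -> int:
        return len(self.drugs)

    def dose_cap(self, drug: str) -> float | None:
        """Min of 0.10*Cmax and IC10 over whichever are provided."""
        caps = []
        if drug in self.cmax:
            caps.append(0.10 * self.cmax[drug])
        if drug in self.ic10:
            caps.append(self.ic10[drug])
        return min(caps) if caps else None

    def dose_for(self, drug: str, code: int) -> float:
        return self.doses[self.drugs.index(drug)][code]


def load_panel(path: str | Path) -> DrugPanel:
    """Read a panel from YAML: ``drugs: {name: {doses: [0, lo, hi], cmax: ..}}``."""
    raw = yaml.safe_load(Path(path).read_text())
    drugs, doses, cmax, ic10 = [], [], {}, {}
    for name, entry in raw["drugs"].items():
        drugs.append(name)
        doses.append(tuple(float(x) for x in entry["doses"]))
        if entry.get("cmax") is not None:
            cmax[name] = float(entry["cmax"])
        if entry.get("ic10") is not None:
            ic10[name] = float(entry["ic10"])
    return DrugPanel(tuple(drugs), tuple(doses), cmax, ic10)


# ---------------------------------------------------------------------------
# design matrix container
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DesignMatrix:
    """Coded dose-level assignments, one row per ex vivo test point.

    ``codes`` is an (n, k) integer array over {0, 1, 2}; ``portion`` tags
    each row as belonging to the two-level factorial or the three-level
    orthogonal-array part of the composite design.
    """

    codes: np.ndarray
    portion: tuple[str, ...]

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes, dtype=np.int8)
        object.__setattr__(self, "codes", codes)
        object.__setattr__(self, "portion", tuple(self.portion))
        if codes.ndim != 2:
            raise ValueError("codes must be 2-D")
        if len(self.portion) != codes.shape[0]:
            raise ValueError("one portion tag per row required")
        if not np.isin(codes, (0, 1, 2)).all():
            raise ValueError("codes must be in {0, 1, 2}")
        for tag in (TWO_LEVEL, THREE_LEVEL):
            sub = codes[[p == tag for p in self.portion]]
            if len(sub) and len(np.unique(sub, axis=0)) != len(sub):
                raise ValueError(f"duplicate rows within {tag} portion")
        two = codes[[p == TWO_LEVEL for p in self.portion]]
        if len(two) and np.any(two == 1):
            raise ValueError("two-level portion may only use codes {0, 2}")

    @property
    def n_rows(self) -> int:
        return self.codes.shape[0]

    @property
    def k(self) -> int:
        return self.codes.shape[1]

    @property
    def numeric(self) -> np.ndarray:
        """Codes mapped to normalized doses {0.0, 0.5, 1.0}."""
        return self.codes.astype(float) / 2.0


# ---------------------------------------------------------------------------
# two-level fractional-factorial portion
# ---------------------------------------------------------------------------

# Generator words per factor count: (n base factors, words over base letters
# A.. defining each added factor).  k=5..10 are the standard minimum-
# aberration fractions; k=11 and 13..16 come from the 32-run fold-over family
# (all words odd length, resolution IV by construction); k=12 is a 2^(12-5)
# resolution-IV set chosen so the composite design's quadratic model matrix
# reaches full rank 91.  Tests re-derive resolution from the built matrix.
_GENERATORS: dict[int, tuple[int, tuple[str, ...]]] = {
    5: (4, ("ABCD",)),
    6: (4, ("ABC", "BCD")),
    7: (4, ("ABC", "BCD", "ACD")),
    8: (4, ("BCD", "ACD", "ABC", "ABD")),
    9: (5, ("BCDE", "ACDE", "ABDE", "ABCE")),
    10: (5, ("ABCD", "ABCE", "ABDE", "ACDE", "BCDE")),
    11: (5, ("ABC", "ABD", "ABE", "ACD", "ACE", "ABCDE")),
    12: (7, ("ABFG", "ABCD", "ADEFG", "ACDG", "ABEG")),
    13: (5, ("ABC", "ABD", "ABE", "ACD", "ACE", "ADE", "BCD", "ABCDE")),
    14: (5, ("ABC", "ABD", "ABE", "ACD", "ACE", "ADE", "BCD", "BCE", "ABCDE")),
    15: (5, ("ABC", "ABD", "ABE", "ACD", "ACE", "ADE", "BCD", "BCE", "BDE", "ABCDE")),
    16: (5, ("ABC", "ABD", "ABE", "ACD", "ACE", "ADE", "BCD", "BCE", "BDE", "CDE", "ABCDE")),
}


def _signs_full_factorial(m: int) -> np.ndarray:
    """All 2^m sign rows (+-1) in standard order, first factor fastest."""
    rows = np.arange(2**m)
    bits = (rows[:, None] >> np.arange(m)) & 1
    return (1 - 2 * bits).astype(np.int8)


def build_two_level_fraction(k: int) -> DesignMatrix:
    """Two-level portion: full factorial for k <= 4, else a stored
    resolution >= IV regular fraction.

    Raises :class:`DesignUnavailableError` when no generator set is stored
    for ``k``; there is deliberately no silent fallback.
    """
    if not 2 <= k <= 16:
        raise DesignUnavailableError(f"two-level portion supports 2 <= k <= 16, got {k}")
    if k <= 4:
        signs = _signs_full_factorial(k)
    else:
        if k not in _GENERATORS:
            raise DesignUnavailableError(f"no stored generator set for k={k}")
        m, words = _GENERATORS[k]
        base = _signs_full_factorial(m)
        extra = [
            np.prod([base[:, ord(ch) - ord("A")] for ch in word], axis=0)
            for word in words
        ]
        signs = np.column_stack([base] + extra).astype(np.int8)
    codes = np.where(signs == 1, 2, 0).astype(np.int8)
    return DesignMatrix(codes, (TWO_LEVEL,) * codes.shape[0])


def min_defining_word_length(codes: np.ndarray) -> int:
    """Resolution of a regular two-level design, computed from the matrix.

    Enumerates every subset of columns whose elementwise product (in +-1
    coding) is constant +1 — the defining contrast subgroup — and returns
    the minimum word length.  Returns an effectively infinite length (k+1)
    for a full factorial, which has no defining words.
    """
    codes = np.asarray(codes)
    k = codes.shape[1]
    signs = np.where(codes == 2, 1, -1)
    best = k + 1
    for r in range(1, k + 1):
        if r >= best:
            break
        for cols in itertools.combinations(range(k), r):
            if np.all(np.prod(signs[:, cols], axis=1) == 1):
                best = min(best, r)
                break
    return best


# ---------------------------------------------------------------------------
# three-level orthogonal-array portion
# ---------------------------------------------------------------------------


def _gf3_array(n_basis: int) -> np.ndarray:
    """Strength-2 orthogonal array OA(3^m, (3^m-1)/2, 3, 2) over GF(3).

    Columns are the dot products of all 3^m points with the projective
    representatives (first nonzero coordinate 1); basis vectors come first
    so any prefix of >= m columns has distinct rows.
    """
    pts = np.array(list(itertools.product(range(3), repeat=n_basis)))
    vecs = []
    for v in itertools.product(range(3), repeat=n_basis):
        arr = np.array(v)
        nz = np.nonzero(arr)[0]
        if len(nz) and arr[nz[0]] == 1:
            vecs.append(arr)
    vecs.sort(key=lambda a: (int((a != 0).sum() != 1), a.tolist()))
    return np.array([[int(p @ v % 3) for v in vecs] for p in pts], dtype=np.int8)


def build_three_level_oa(k: int) -> DesignMatrix:
    """Smallest standard three-level orthogonal array covering k columns:
    the 9-run array for k <= 4, the 27-run array for 5 <= k <= 13."""
    if k < 2:
        raise DesignUnavailableError("need at least 2 factors")
    if k > 13:
        raise DesignUnavailableError(
            f"no three-level orthogonal array stored beyond 13 columns (got k={k})"
        )
    full = _gf3_array(2) if k <= 4 else _gf3_array(3)
    codes = full[:, :k]
    return DesignMatrix(codes, (THREE_LEVEL,) * codes.shape[0])


# ---------------------------------------------------------------------------
# composite design
# ---------------------------------------------------------------------------


def generate_oacd(k: int) -> DesignMatrix:
    """Composite design: two-level fraction followed by the three-level
    orthogonal array.  Deterministic; 155 rows for k = 12."""
    two = build_two_level_fraction(k)
    three = build_three_level_oa(k)
    return DesignMatrix(
        np.vstack([two.codes, three.codes]),
        two.portion + three.portion,
    )


def map_levels_to_doses(design: DesignMatrix, panel: DrugPanel) -> pd.DataFrame:
    """Per-row molar concentrations for every drug (code 0 -> 0 M).

    Re-validates the panel's dose caps so a cap violation is reported with
    the offending drug even for panels constructed without caps.
    """
    if design.k != panel.k:
        raise ValueError(
            f"design has {design.k} columns but panel has {panel.k} drugs"
        )
    for name in panel.drugs:
        cap = panel.dose_cap(name)
        top = panel.dose_for(name, 2)
        if cap is not None and top > cap * (1 + 1e-12):
            raise DoseCapError(f"{name}: top dose {top:g} M exceeds cap {cap:g} M")
    dose_table = np.array(panel.doses)  # (k, 3)
    conc = dose_table[np.arange(design.k)[None, :], design.codes.astype(int)]
    return pd.DataFrame(conc, columns=list(panel.drugs))


# ---------------------------------------------------------------------------
# text round-trip
# ---------------------------------------------------------------------------


def write_design(design: DesignMatrix, path: str | Path, panel: DrugPanel | None = None) -> None:
    """Write codes as CSV (columns = drugs or f0..f{k-1}) with a JSON
    sidecar carrying portion tags and panel metadata."""
    path = Path(path)
    cols = list(panel.drugs) if panel is not None else [f"f{i}" for i in range(design.k)]
    df = pd.DataFrame(design.codes, columns=cols)
    df.insert(0, "row", np.arange(design.n_rows))
    df.to_csv(path, index=False)
    sidecar = {
        "portion": list(design.portion),
        "drugs": cols,
        "numeric_code": {str(c): v for c, v in NUMERIC_CODE.items()},
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_design(path: str | Path) -> DesignMatrix:
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    codes = df[sidecar["drugs"]].to_numpy(dtype=np.int8)
    return DesignMatrix(codes, tuple(sidecar["portion"]))
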