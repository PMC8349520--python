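"""Morphometric ratio characters and the combined character matrix.

Builds size-decorrelated log-ratio characters from specimen measurements
(inter-landmark segment lengths, possibly computed from raw 3D landmark
coordinates), summarizes intraspecific variation as 95% confidence
intervals of species means, applies the size-correlation filter, and
holds the combined continuous + discrete matrix with its scaling state.

Continuous cells are (mean, lo, hi, n) tuples; discrete cells are state
sets (polymorphism) or missing.  Scaling constants are estimated on the
extant species' means only and applied identically to every row,
including query (fossil) rows, so that fossils are measured on the same
scale they are placed with.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CharacterError",
    "RatioCharacterDefinition",
    "ScalingSpec",
    "CharacterMatrix",
    "compute_segments",
    "centroid_size",
    "log_ratio",
    "size_correlation_filter",
    "summarize_species",
    "build_continuous_matrix",
]

Z95 = 1.959964  # normal 97.5% quantile: CI assumes a normal distribution


class CharacterError(ValueError):
    pass


@dataclass(frozen=True)
class RatioCharacterDefinition:
    """A log-ratio character: log(sum(numerator) / sum(denominator)).

    ``size_correlation`` records the Pearson correlation of the log-ratio
    with log size (filled in by :func:`size_correlation_filter`).
    """

    name: str
    numerator: tuple[str, ...]
    denominator: tuple[str, ...]
    size_correlation: Optional[float] = None

    def __post_init__(self):
        if not self.numerator or not self.denominator:
            raise CharacterError(f"{self.name}: empty numerator or denominator")


@dataclass
class ScalingSpec:
    """Per-character affine scaling: scaled = (x - location) / scale."""

    method: str  # 'raw' | 'range' | 'zscore'
    location: pd.Series
    scale: pd.Series

    def __post_init__(self):
        if self.method not in ("raw", "range", "zscore"):
            raise CharacterError(f"unknown scaling method {self.method!r}")
        if (self.scale <= 0).any():
            bad = list(self.scale.index[self.scale <= 0])
            raise CharacterError(f"non-positive scale for characters {bad}")


# ---------------------------------------------------------------------------
# Measurement-level operations
# ---------------------------------------------------------------------------


def compute_segments(
    landmarks: Mapping[str, Sequence[float]],
    segment_defs: Mapping[str, tuple[str, str]],
) -> dict[str, float]:
    """Euclidean inter-landmark distances; missing endpoints give NaN."""
    out = {}
    for name, (a, b) in segment_defs.items():
        if a not in landmarks or b not in landmarks:
            out[name] = math.nan
            continue
        pa, pb = np.asarray(landmarks[a], float), np.asarray(landmarks[b], float)
        if not (np.isfinite(pa).all() and np.isfinite(pb).all()):
            raise CharacterError(f"non-finite coordinates for segment {name}")
        out[name] = float(np.linalg.norm(pa - pb))
    return out


def centroid_size(landmarks: Mapping[str, Sequence[float]] | np.ndarray) -> float:
    """Square root of summed squared distances of landmarks to their centroid."""
    pts = (
        np.asarray(list(landmarks.values()), float)
        if isinstance(landmarks, Mapping)
        else np.asarray(landmarks, float)
    )
    if pts.shape[0] < 2:
        raise CharacterError("centroid size needs at least 2 landmarks")
    centered = pts - pts.mean(axis=0)
    return float(np.sqrt((centered**2).sum()))


def log_ratio(values: Mapping[str, float], definition: RatioCharacterDefinition) -> float:
    """Natural log of (sum of numerator segments / sum of denominator segments).

    Returns NaN if any required segment is missing; raises for non-positive
    segment values.
    """
    parts = []
    for group in (definition.numerator, definition.denominator):
        total = 0.0
        for seg in group:
            v = values.get(seg, math.nan)
            if isinstance(v, float) and math.isnan(v):
                return math.nan
            if v <= 0:
                raise CharacterError(
                    f"{definition.name}: segment {seg} must be positive, got {v}"
                )
            total += v
        parts.append(total)
    return math.log(parts[0] / parts[1])


def size_correlation_filter(
    char_values: Sequence[float],
    log_sizes: Sequence[float],
    threshold: float = 0.3,
) -> tuple[float, bool]:
    """Pearson r between a log-ratio character and log size, with keep flag.

    Characters are kept only when -threshold < r < threshold (strict), so
    only weakly size-correlated ratios enter the matrix.
    """
    x = np.asarray(char_values, float)
    y = np.asarray(log_sizes, float)
    keep_mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep_mask], y[keep_mask]
    if x.size < 3:
        raise CharacterError("correlation needs at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise CharacterError("correlation undefined: zero variance")
    r = float(np.corrcoef(x, y)[0, 1])
    return r, (-threshold < r < threshold)


def summarize_species(values: Sequence[float], z: float = Z95) -> tuple[float, float, float, int]:
    """(mean, lo, hi, n): normal 95% CI of the mean of per-specimen values.

    The half-width is z * sd / sqrt(n) with the n-1 sample standard
    deviation; a single specimen gives a degenerate interval at its value.
    """
    x = np.asarray([v for v in values if not (isinstance(v, float) and math.isnan(v))], float)
    if x.size == 0:
        raise CharacterError("cannot summarize an empty sample")
    mean = float(x.mean())
    if x.size == 1:
        return mean, mean, mean, 1
    half = z * float(x.std(ddof=1)) / math.sqrt(x.size)
    return mean, mean - half, mean + half, int(x.size)


def build_continuous_matrix(
    specimen_values: pd.DataFrame,
    species_of: Mapping[str, str],
    z: float = Z95,
) -> "CharacterMatrix":
    """Assemble a continuous matrix from a specimen x character table.

    ``specimen_values`` is indexed by specimen id; ``species_of`` maps
    specimen id -> species label.
    """
    chars = list(specimen_values.columns)
    species = sorted(set(species_of[s] for s in specimen_values.index))
    mean = pd.DataFrame(np.nan, index=species, columns=chars)
    lo = mean.copy()
    hi = mean.copy()
    n = pd.DataFrame(0, index=species, columns=chars, dtype=int)
    groups = specimen_values.groupby(
        specimen_values.index.map(species_of.__getitem__)
    )
    for sp, block in groups:
        for ch in chars:
            vals = block[ch].dropna().to_numpy()
            if vals.size == 0:
                continue
            m, l, h, k = summarize_species(vals, z=z)
            mean.loc[sp, ch], lo.loc[sp, ch], hi.loc[sp, ch] = m, l, h
            n.loc[sp, ch] = k
    return CharacterMatrix(
        cont_mean=mean, cont_lo=lo, cont_hi=hi, cont_n=n,
        disc=pd.DataFrame(index=species), ordered=pd.Series(dtype=bool),
    )


# ---------------------------------------------------------------------------
# The combined matrix
# ---------------------------------------------------------------------------


def parse_state_set(text: str) -> Optional[frozenset[int]]:
    """Parse a state-set string: '1', '0/1', '{01}', '?' or '-' (missing)."""
    text = str(text).strip()
    if text in ("?", "-", "", "nan"):
        return None
    if text.startswith("{") and text.endswith("}"):
        inner = text[1:-1].replace(",", "").replace(" ", "")
        return frozenset(int(c) for c in inner)
    if "/" in text:
        return frozenset(int(p) for p in text.split("/"))
    return frozenset((int(float(text)),))


def format_state_set(states: Optional[frozenset[int]]) -> str:
    if states is None:
        return "?"
    return "/".join(str(s) for s in sorted(states))


@dataclass
class CharacterMatrix:
    """Combined continuous + discrete species x character matrix.

    Continuous characters live in four aligned DataFrames (mean, lo, hi,
    n); discrete characters in one DataFrame of frozensets (or None for
    missing), with a per-character ``ordered`` flag.  ``queries`` names the
    rows that are fossils/queries and are excluded from scaling constants
    and informativeness counts.
    """

    cont_mean: pd.DataFrame
    cont_lo: pd.DataFrame
    cont_hi: pd.DataFrame
    cont_n: pd.DataFrame
    disc: pd.DataFrame
    ordered: pd.Series
    queries: frozenset[str] = frozenset()
    scaling: Optional[ScalingSpec] = None

    def __post_init__(self):
        self.queries = frozenset(self.queries)
        self._validate()

    def _validate(self):
        for df in (self.cont_lo, self.cont_hi, self.cont_n):
            if not df.index.equals(self.cont_mean.index):
                raise CharacterError("continuous frames must share the species index")
        if not self.disc.index.equals(self.cont_mean.index):
            raise CharacterError("discrete and continuous frames must share species")
        mask = self.cont_mean.notna().to_numpy(dtype=bool)
        if mask.size and mask.any():
            lo = self.cont_lo.to_numpy(float)
            hi = self.cont_hi.to_numpy(float)
            mean = self.cont_mean.to_numpy(float)
            if not ((lo[mask] <= mean[mask] + 1e-12) & (mean[mask] <= hi[mask] + 1e-12)).all():
                raise CharacterError("continuous cells must satisfy lo <= mean <= hi")
            one = (self.cont_n.to_numpy(int) == 1) & mask
            if one.any():
                if not np.allclose(lo[one], mean[one]) or not np.allclose(hi[one], mean[one]):
                    raise CharacterError("n = 1 cells must have a degenerate interval")
        for ch in self.disc.columns:
            for cell in self.disc[ch]:
                if cell is not None and not isinstance(cell, frozenset):
                    raise CharacterError(f"discrete cells must be frozensets or None ({ch})")
                if isinstance(cell, frozenset) and not cell:
                    raise CharacterError(f"empty state set in character {ch}")

    # -- basic views -------------------------------------------------------

    @property
    def species(self) -> list[str]:
        return list(self.cont_mean.index)

    @property
    def extant(self) -> list[str]:
        return [s for s in self.species if s not in self.queries]

    @property
    def continuous_names(self) -> list[str]:
        return list(self.cont_mean.columns)

    @property
    def discrete_names(self) -> list[str]:
        return list(self.disc.columns)

    @property
    def n_characters(self) -> int:
        return len(self.continuous_names) + len(self.discrete_names)

    def copy(self) -> "CharacterMatrix":
        return CharacterMatrix(
            cont_mean=self.cont_mean.copy(), cont_lo=self.cont_lo.copy(),
            cont_hi=self.cont_hi.copy(), cont_n=self.cont_n.copy(),
            disc=self.disc.copy(), ordered=self.ordered.copy(),
            queries=self.queries, scaling=self.scaling,
        )

    def subset(self, species: Iterable[str]) -> "CharacterMatrix":
        idx = list(species)
        return CharacterMatrix(
            cont_mean=self.cont_mean.loc[idx], cont_lo=self.cont_lo.loc[idx],
            cont_hi=self.cont_hi.loc[idx], cont_n=self.cont_n.loc[idx],
            disc=self.disc.loc[idx], ordered=self.ordered.copy(),
            queries=self.queries & frozenset(idx), scaling=self.scaling,
        )

    def without(self, species: str) -> "CharacterMatrix":
        return self.subset([s for s in self.species if s != species])

    # -- informativeness ---------------------------------------------------

    def informative_mask(self) -> pd.Series:
        """Parsimony-informativeness flag per discrete character.

        A character is informative iff at least two of its states are each
        observed fixed (non-polymorphically) in two or more species.
        Polymorphic observations do not count toward any state's tally.
        """
        flags = {}
        for ch in self.disc.columns:
            fixed_counts: dict[int, int] = {}
            for cell in self.disc[ch]:
                if isinstance(cell, frozenset) and len(cell) == 1:
                    (state,) = cell
                    fixed_counts[state] = fixed_counts.get(state, 0) + 1
            flags[ch] = sum(1 for c in fixed_counts.values() if c >= 2) >= 2
        return pd.Series(flags, dtype=bool).reindex(self.disc.columns)

    def drop_uninformative(self) -> "CharacterMatrix":
        keep = self.informative_mask()
        out = self.copy()
        out.disc = out.disc.loc[:, keep[keep].index]
        out.ordered = out.ordered.reindex(out.disc.columns).fillna(False)
        return out

    # -- scaling -----------------------------------------------------------

    def scale(self, method: str, extant_only: bool = True) -> tuple["CharacterMatrix", ScalingSpec]:
        """Affine-rescale continuous characters; returns (matrix, spec).

        Constants come from the extant species' means (``extant_only``),
        and the same transform is applied to mean, lo and hi of every row.
        'raw' is the identity; 'range' makes the extant means span exactly
        one unit; 'zscore' gives the extant means unit sample variance.
        """
        ref = self.cont_mean.loc[self.extant] if extant_only else self.cont_mean
        if method == "raw":
            location = pd.Series(0.0, index=self.cont_mean.columns)
            scale = pd.Series(1.0, index=self.cont_mean.columns)
        elif method == "range":
            location = ref.min()
            scale = ref.max() - ref.min()
        elif method == "zscore":
            location = ref.mean()
            scale = ref.std(ddof=1)
        else:
            raise CharacterError(f"unknown scaling method {method!r}")
        bad = scale.index[(scale <= 0) | ~np.isfinite(scale)]
        if len(bad):
            raise CharacterError(f"zero range/variance in characters {list(bad)}")
        spec = ScalingSpec(method=method, location=location, scale=scale)
        out = self.copy()
        out.cont_mean = (self.cont_mean - location) / scale
        out.cont_lo = (self.cont_lo - location) / scale
        out.cont_hi = (self.cont_hi - location) / scale
        out.scaling = spec
        return out, spec

    def unscale(self, spec: ScalingSpec) -> "CharacterMatrix":
        out = self.copy()
        out.cont_mean = self.cont_mean * spec.scale + spec.location
        out.cont_lo = self.cont_lo * spec.scale + spec.location
        out.cont_hi = self.cont_hi * spec.scale + spec.location
        out.scaling = None
        return out

    # -- scoring views -----------------------------------------------------

    def interval_blocks(self, ci: bool = True):
        """(lo, hi) arrays for continuous + ordered-discrete characters.

        Continuous cells give their 95% CI (``ci=True``) or degenerate
        point intervals at the mean; ordered discrete cells give their
        spanning interval [min state, max state]; missing cells are
        unbounded.  Returns (names, lo, hi) with rows ordered as
        ``self.species``.
        """
        names = list(self.continuous_names)
        if ci:
            lo = self.cont_lo.to_numpy(float).copy()
            hi = self.cont_hi.to_numpy(float).copy()
        else:
            lo = self.cont_mean.to_numpy(float).copy()
            hi = lo.copy()
        miss = ~np.isfinite(lo) | ~np.isfinite(hi)
        lo[miss], hi[miss] = -np.inf, np.inf
        ord_cols = [c for c in self.disc.columns if bool(self.ordered.get(c, False))]
        if ord_cols:
            olo = np.full((len(self.species), len(ord_cols)), -np.inf)
            ohi = np.full_like(olo, np.inf)
            for j, ch in enumerate(ord_cols):
                for i, cell in enumerate(self.disc[ch]):
                    if isinstance(cell, frozenset):
                        olo[i, j], ohi[i, j] = min(cell), max(cell)
            lo = np.hstack([lo, olo])
            hi = np.hstack([hi, ohi])
            names += ord_cols
        return names, lo, hi

    def unordered_blocks(self):
        """(names, allowed) for unordered discrete characters.

        ``allowed`` is a boolean (species x chars x states) array: True
        where the state is permitted for the cell.  Missing cells permit
        every observed state of their character.
        """
        cols = [c for c in self.disc.columns if not bool(self.ordered.get(c, False))]
        if not cols:
            return [], np.zeros((len(self.species), 0, 1), bool)
        state_space = []
        for ch in cols:
            observed = set()
            for cell in self.disc[ch]:
                if isinstance(cell, frozenset):
                    observed |= cell
            state_space.append(sorted(observed) or [0])
        smax = max(len(s) for s in state_space)
        allowed = np.zeros((len(self.species), len(cols), smax), bool)
        for j, (ch, states) in enumerate(zip(cols, state_space)):
            index = {s: k for k, s in enumerate(states)}
            for i, cell in enumerate(self.disc[ch]):
                if isinstance(cell, frozenset):
                    for s in cell:
                        allowed[i, j, index[s]] = True
                else:
                    allowed[i, j, : len(states)] = True
        return cols, allowed

    def missing_fraction(self) -> pd.Series:
        """Fraction of species with a missing cell, per character."""
        cont = self.cont_mean.isna().mean()
        disc = self.disc.isna().mean() if len(self.disc.columns) else pd.Series(dtype=float)
        return pd.concat([cont, disc])

    # -- I/O ---------------------------------------------------------------

    def to_csv(self, path) -> None:
        """Native long-format CSV: one row per species x character."""
        rows = []
        for sp in self.species:
            for ch in self.continuous_names:
                rows.append({
                    "species": sp, "character": ch, "kind": "continuous",
                    "ordered": True,
                    "mean": self.cont_mean.at[sp, ch], "lo": self.cont_lo.at[sp, ch],
                    "hi": self.cont_hi.at[sp, ch], "n": self.cont_n.at[sp, ch],
                    "states": "",
                })
            for ch in self.discrete_names:
                rows.append({
                    "species": sp, "character": ch, "kind": "discrete",
                    "ordered": bool(self.ordered.get(ch, False)),
                    "mean": "", "lo": "", "hi": "", "n": "",
                    "states": format_state_set(self.disc.at[sp, ch]),
                })
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, queries: Iterable[str] = ()) -> "CharacterMatrix":
        df = pd.read_csv(path, dtype={"states": str}, keep_default_na=False)
        species = list(dict.fromkeys(df["species"]))
        cont = df[df["kind"] == "continuous"]
        disc = df[df["kind"] == "discrete"]
        cont_chars = list(dict.fromkeys(cont["character"]))
        disc_chars = list(dict.fromkeys(disc["character"]))
        mean = pd.DataFrame(np.nan, index=species, columns=cont_chars)
        lo, hi = mean.copy(), mean.copy()
        n = pd.DataFrame(0, index=species, columns=cont_chars, dtype=int)
        for _, row in cont.iterrows():
            if row["mean"] == "":
                continue
            sp, ch = row["species"], row["character"]
            mean.at[sp, ch] = float(row["mean"])
            lo.at[sp, ch] = float(row["lo"])
            hi.at[sp, ch] = float(row["hi"])
            n.at[sp, ch] = int(float(row["n"]))
        dmat = pd.DataFrame(None, index=species, columns=disc_chars, dtype=object)
        ordered = {}
        for _, row in disc.iterrows():
            dmat.at[row["species"], row["character"]] = parse_state_set(row["states"])
            ordered[row["character"]] = str(row["ordered"]).lower() in ("true", "1")
        dmat = dmat.where(dmat.notna(), None)
        return cls(
            cont_mean=mean, cont_lo=lo, cont_hi=hi, cont_n=n, disc=dmat,
            ordered=pd.Series(ordered, dtype=bool).reindex(disc_chars).fillna(False)
            if disc_chars else pd.Series(dtype=bool),
            queries=frozenset(queries),
        )

    # TNT-dialect and NEXUS export live in matrix_io to keep this class lean.


def _as_object_frame(df: pd.DataFrame) -> pd.DataFrame:
    out = df.astype(object)
    return out.where(out.notna(), None)
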