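"""Replicated stable-isotope measurements and example webs."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .foodweb import FoodWeb

__all__ = ["IsotopeDataset", "grassland_web"]


class IsotopeDataset:
    """Per species x element replicated isotope measurements (per mil).

    Wraps a long-format table ``species, element, value`` plus optional
    per-resource elemental concentrations ``species, element, concentration``
    (default 1 everywhere, i.e. pure isotopic mixing).
    """

    def __init__(
        self,
        measurements: pd.DataFrame,
        concentrations: pd.DataFrame | None = None,
    ):
        req = {"species", "element", "value"}
        if not req.issubset(measurements.columns):
            raise ValueError(f"measurements need columns {sorted(req)}")
        m = measurements[["species", "element", "value"]].copy()
        m["value"] = m["value"].astype(float)
        self._m = m.reset_index(drop=True)
        if concentrations is not None:
            creq = {"species", "element", "concentration"}
            if not creq.issubset(concentrations.columns):
                raise ValueError(f"concentrations need columns {sorted(creq)}")
            c = concentrations[["species", "element", "concentration"]].copy()
            c["concentration"] = c["concentration"].astype(float)
            if (c["concentration"] <= 0).any():
                raise ValueError("concentrations must be strictly positive")
            self._c = c.reset_index(drop=True)
        else:
            self._c = None

    # -- accessors --------------------------------------------------------
    @property
    def measurements(self) -> pd.DataFrame:
        return self._m.copy()

    @property
    def concentrations(self) -> pd.DataFrame | None:
        return None if self._c is None else self._c.copy()

    @property
    def elements(self) -> tuple[str, ...]:
        return tuple(sorted(self._m["element"].unique()))

    @property
    def species(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for s in self._m["species"]:
            seen.setdefault(s)
        return tuple(seen)

    def _cells(self) -> dict:
        # lazy (species, element) -> replicate array cache
        cache = getattr(self, "_cell_cache", None)
        if cache is None:
            cache = {
                key: grp["value"].to_numpy()
                for key, grp in self._m.groupby(["species", "element"], sort=False)
            }
            self._cell_cache = cache
        return cache

    def values(self, species: str, element: str) -> np.ndarray:
        return self._cells().get((species, element), np.empty(0))

    def n_replicates(self, species: str, element: str) -> int:
        return len(self.values(species, element))

    def mean(self, species: str, element: str) -> float:
        return float(self.values(species, element).mean())

    def var(self, species: str, element: str) -> float:
        v = self.values(species, element)
        return float(v.var(ddof=1)) if len(v) > 1 else 0.0

    def concentration(self, species: str, element: str) -> float:
        if self._c is None:
            return 1.0
        sel = (self._c["species"] == species) & (self._c["element"] == element)
        hit = self._c.loc[sel, "concentration"]
        return float(hit.iloc[0]) if len(hit) else 1.0

    # -- transformations ---------------------------------------------------
    def subset(self, keep: set[str] | list[str]) -> "IsotopeDataset":
        keep = set(keep)
        m = self._m[self._m["species"].isin(keep)]
        c = None if self._c is None else self._c[self._c["species"].isin(keep)]
        return IsotopeDataset(m, c)

    def pooled(self, mapping: dict[str, str]) -> "IsotopeDataset":
        """Pool replicates of species mapped to the same node label.

        Used by trophospecies aggregation: the pooled node holds the union of
        its members' replicates.  Concentrations of pooled members are
        averaged (equal weight per member).
        """
        m = self._m.copy()
        m["species"] = m["species"].map(lambda s: mapping.get(s, s))
        c = None
        if self._c is not None:
            c = self._c.copy()
            c["species"] = c["species"].map(lambda s: mapping.get(s, s))
            c = (
                c.groupby(["species", "element"], as_index=False)["concentration"]
                .mean()
            )
        return IsotopeDataset(m, c)

    # -- IO ----------------------------------------------------------------
    @classmethod
    def from_csv(cls, path, concentrations_path=None) -> "IsotopeDataset":
        m = pd.read_csv(path)
        c = None if concentrations_path is None else pd.read_csv(concentrations_path)
        return cls(m, c)

    def to_csv(self, path, concentrations_path=None) -> None:
        self._m.to_csv(path, index=False)
        if concentrations_path is not None and self._c is not None:
            self._c.to_csv(concentrations_path, index=False)

    def __repr__(self) -> str:
        return (
            f"IsotopeDataset({len(self.species)} species, "
            f"elements={list(self.elements)}, {len(self._m)} measurements)"
        )


def grassland_web(variant: str = "original") -> FoodWeb:
    """The seven-node Kenyan wooded-grassland web used as a worked example.

    Nodes: C3 trees/shrubs, C4 grasses, arboreal and terrestrial prey
    arthropods, arboreal and terrestrial predatory arthropods, and an
    arboreal gecko.  ``variant`` selects the candidate topology:

    - ``"original"``: literature topology (10 links);
    - ``"gecko_igp"``: adds the intraguild link gecko -> arboreal predatory
      arthropods;
    - ``"all_predators"``: all links among predators except predatory
      arthropods eating geckos.
    """
    c3, c4 = "C3 plants", "C4 plants"
    ap, tp = "arboreal prey", "terrestrial prey"
    apa, tpa = "arboreal predators", "terrestrial predators"
    gecko = "gecko"
    species = (c3, c4, ap, tp, apa, tpa, gecko)
    links = [
        (ap, c3), (ap, c4),
        (tp, c3), (tp, c4),
        (apa, ap), (apa, tp),
        (tpa, ap), (tpa, tp),
        (gecko, ap), (gecko, tp),
    ]
    if variant == "original":
        pass
    elif variant == "gecko_igp":
        links.append((gecko, apa))
    elif variant == "all_predators":
        links += [(gecko, apa), (gecko, tpa), (apa, tpa), (tpa, apa)]
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return FoodWeb(species, tuple(links))
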