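"""Gut metabolic modules (GMMs): detection from KO profiles and enrichment.

A GMM is a metabolic pathway expressed as an ordered series of enzymatic
steps, each step a set of alternative KEGG ortholog (KO) identifiers, with
optionally several alternative paths through the module.  A species is deemed
to carry a module if its KO repertoire covers at least two-thirds of the
steps of some path -- all steps for modules of three or fewer steps.

Enrichment of modules among direction-stratified, p-value-ranked species
association results is tested with a one-sided rank-sum statistic: carriers
of an enriched module concentrate at the low-p end of the ranking.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

_KO_RE = re.compile(r"^K\d{5}$")

Path = tuple[frozenset, ...]


@dataclass(frozen=True)
class GMMDefinition:
    """One metabolic module: id, human-readable name, and >=1 alternative
    paths, each an ordered tuple of steps (frozensets of KO ids)."""

    id: str
    name: str
    paths: tuple[Path, ...]

    def __post_init__(self) -> None:
        if not self.paths:
            raise ValueError(f"module {self.id} has no paths")
        for path in self.paths:
            if not path or any(len(step) == 0 for step in path):
                raise ValueError(f"module {self.id} has an empty path or step")

    @property
    def all_kos(self) -> frozenset:
        out: set = set()
        for path in self.paths:
            for step in path:
                out |= step
        return frozenset(out)


def required_steps(n_steps: int) -> int:
    """Number of covered steps a path needs for the module to count as present.

    All steps for paths of three or fewer steps; otherwise at least two-thirds
    of the steps, rounded up ("at least two-thirds" is a lower bound).
    """
    if n_steps <= 3:
        return n_steps
    return math.ceil(2.0 * n_steps / 3.0)


def species_has_gmm(kos: Iterable, gmm: GMMDefinition) -> bool:
    """Apply the coverage rule: a step is covered if the species' KO set
    intersects it; the module is present if any path reaches its required
    step count.  An empty KO set yields False."""
    ko_set = set(kos)
    if not ko_set:
        return False
    for path in gmm.paths:
        covered = sum(1 for step in path if ko_set & step)
        if covered >= required_steps(len(path)):
            return True
    return False


def annotate_species(
    ko_table: pd.DataFrame | Mapping[str, Iterable],
    gmms: Sequence[GMMDefinition],
) -> pd.DataFrame:
    """Boolean species x module presence matrix.

    ``ko_table`` is either a long DataFrame with columns ``species_id`` and
    ``ko_id`` (duplicate pairs rejected) or a mapping species -> KO iterable.
    """
    if isinstance(ko_table, pd.DataFrame):
        if ko_table.duplicated(subset=["species_id", "ko_id"]).any():
            raise ValueError("duplicate (species_id, ko_id) rows in KO table")
        sets = {sp: set(sub) for sp, sub in ko_table.groupby("species_id", observed=True)["ko_id"]}
    else:
        sets = {sp: set(v) for sp, v in ko_table.items()}
        if len(sets) != len(ko_table):
            raise ValueError("duplicate species ids in KO mapping")
    mat = {
        g.id: [species_has_gmm(sets[sp], g) for sp in sets] for g in gmms
    }
    return pd.DataFrame(mat, index=pd.Index(list(sets), name="species_id"))


# ---------------------------------------------------------------------------
# Flat-file format
# ---------------------------------------------------------------------------
# Module header: "<id>\t<name>"; then one line per step with comma-separated
# KO ids; alternative paths separated by a line "//"; modules separated by a
# blank line.  Example:
#
#   MF0001	propionate production
#   K00001,K00002
#   K00010
#   //
#   K00020
#   K00021,K00022
#
#   MF0002	threonine degradation
#   K00030
#   K00031

def parse_gmm_text(text: str) -> list[GMMDefinition]:
    defs: list[GMMDefinition] = []
    blocks = [b for b in re.split(r"\n\s*\n", text.strip()) if b.strip()]
    for block in blocks:
        lines = [ln.strip() for ln in block.splitlines() if ln.strip()]
        header = lines[0].split("\t")
        if len(header) < 2:
            raise ValueError(f"malformed module header: {lines[0]!r}")
        mid, name = header[0], header[1]
        paths: list[Path] = []
        steps: list[frozenset] = []
        for ln in lines[1:]:
            if ln == "//":
                paths.append(tuple(steps))
                steps = []
            else:
                kos = frozenset(k.strip() for k in ln.split(",") if k.strip())
                steps.append(kos)
        paths.append(tuple(steps))
        defs.append(GMMDefinition(id=mid, name=name, paths=tuple(paths)))
    return defs


def read_gmm_file(path) -> list[GMMDefinition]:
    with open(path, encoding="utf-8") as fh:
        return parse_gmm_text(fh.read())


def format_gmm_text(gmms: Sequence[GMMDefinition]) -> str:
    blocks = []
    for g in gmms:
        lines = [f"{g.id}\t{g.name}"]
        for i, path in enumerate(g.paths):
            if i:
                lines.append("//")
            lines.extend(",".join(sorted(step)) for step in path)
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + "\n"


def write_gmm_file(gmms: Sequence[GMMDefinition], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(format_gmm_text(gmms))


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------

def gmm_enrichment(
    results: pd.DataFrame,
    presence: pd.DataFrame,
    direction: str,
    min_carriers: int = 3,
    fdr_adjust=None,
) -> pd.DataFrame:
    """Rank-sum enrichment of modules among one direction's associations.

    ``results`` must hold one row per species with columns ``feature``,
    ``rho`` and ``p`` (extended-model associations for one exposure);
    ``presence`` is the boolean species x module matrix.  Species are
    restricted to the requested correlation sign and ranked by ascending p;
    for each module, carriers' p-values are compared with non-carriers' by a
    one-sided Mann-Whitney test (carriers smaller).  The normalized score is
    the standardized rank-sum statistic; q-values are BH across tested
    modules within the direction.
    """
    if direction not in ("positive", "negative"):
        raise ValueError("direction must be 'positive' or 'negative'")
    if fdr_adjust is None:
        from .association import bh_adjust as fdr_adjust
    sign = 1.0 if direction == "positive" else -1.0
    sub = results[np.sign(results["rho"]) == sign]
    sub = sub.set_index("feature")["p"]
    rows = []
    for mid in presence.columns:
        carriers = presence.index[presence[mid]]
        in_stratum = sub.index.intersection(carriers)
        out_stratum = sub.index.difference(carriers)
        n1, n2 = len(in_stratum), len(out_stratum)
        if n1 < min_carriers or n2 < min_carriers:
            warnings.warn(f"module {mid}: too few carriers/non-carriers in {direction} stratum; skipped")
            continue
        p_in = sub.loc[in_stratum].to_numpy()
        p_out = sub.loc[out_stratum].to_numpy()
        res = stats.mannwhitneyu(p_in, p_out, alternative="less")
        mu = n1 * n2 / 2.0
        sd = np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
        score = (res.statistic - mu) / sd if sd > 0 else 0.0
        rows.append((mid, direction, n1, -score, float(res.pvalue)))
    out = pd.DataFrame(rows, columns=["gmm_id", "direction", "n_carriers", "score", "p"])
    if len(out):
        out["q"] = fdr_adjust(out["p"].to_numpy())
    else:
        out["q"] = pd.Series(dtype=float)
    return out
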