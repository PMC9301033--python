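"""Per-generation population analytics.

Two summaries characterize an evolution run: the mean molecular weight of
the compounds that pass the pharmacophore filter (computed over passers
only), and the fraction of the *total* population whose shape+electrostatic
combo score reaches each configured threshold (computed over everyone) —
the two denominators are deliberately different, so a run can be judged
both on the quality of its filtered compounds and on whole-population
enrichment.  "Reaches a threshold" means >= (inclusive), configurable.
"""

from __future__ import annotations

import math
from collections.abc import Mapping

import numpy as np
import pandas as pd
from rdkit.Chem import Descriptors

from .chemio import MoleculeRecord
from .evolve import GenerationRecord

DEFAULT_THRESHOLDS = (0.50, 0.75, 1.00)


def molecular_weight(molecule: MoleculeRecord) -> float:
    """Average molecular weight in Da, implicit hydrogens included."""
    return float(Descriptors.MolWt(molecule.mol))


def generation_metrics(
    generations: list[GenerationRecord],
    pharmacophore_pass: Mapping[str, bool],
    combo_scores: Mapping[str, float],
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    strict: bool = False,
) -> pd.DataFrame:
    """One metrics row per generation.

    ``pharmacophore_pass`` and ``combo_scores`` map member names to filter
    outcomes and best et_combo values (all members must be covered).  Mean
    molecular weight is reported over passers only and is NaN when no
    member passes; enrichment fractions count the whole generation, with
    ``combo >= t`` (or ``>`` when ``strict``).
    """
    rows = []
    for rec in generations:
        names = [m.name for m in rec.members]
        missing = [n for n in names if n not in combo_scores]
        if missing:
            raise ValueError(f"combo scores missing for members: {missing[:3]}")
        combos = np.array([float(combo_scores[n]) for n in names])
        passers = [m for m in rec.members if pharmacophore_pass.get(m.name, False)]
        mw = (
            float(np.mean([molecular_weight(m.record) for m in passers]))
            if passers
            else math.nan
        )
        row = {
            "generation": rec.index,
            "population": len(names),
            "n_pass": len(passers),
            "mean_mw_passers": mw,
        }
        for t in thresholds:
            hits = (combos > t) if strict else (combos >= t)
            row[f"frac_combo_ge_{t:.2f}"] = float(hits.mean()) if len(combos) else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def combo_histogram(
    combo_scores, bin_width: float = 0.1, upper: float = 2.0
) -> pd.DataFrame:
    """Binned counts of combo scores on the 0..2 scale (testable table form)."""
    values = np.asarray(list(combo_scores), dtype=float)
    edges = np.arange(0.0, upper + bin_width / 2, bin_width)
    counts, _ = np.histogram(values, bins=edges)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )
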