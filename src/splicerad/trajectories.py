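"""Isoform PSI trajectories between nonradiating lineages and radiations.

For each isoform and each radiation, the mean PSI over all samples of the
nonradiating (NR) group and over all samples of the radiation are compared
and, together with presence calls, mapped to a trajectory class:

======================  =========================================
class                   rule (t = PSI-difference threshold, 0.2)
======================  =========================================
stable-ancestral        present in NR, |dPSI| <= t
ancestral-gain          present in NR, dPSI > t
ancestral-loss          present in NR, dPSI < -t
novel-low               absent in NR, present in radiation, dPSI <= t
novel-gain              absent in NR, present in radiation, dPSI > t
absent                  absent in both groups
======================  =========================================

dPSI = mean PSI(radiation) - mean PSI(NR); when the isoform is absent in
NR its NR mean is taken as 0.  "Absent" means failing the presence rule
(threshold + replicate fraction), not a literal zero, so that sampling
zeros at low depth do not masquerade as novelty.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import FormatError
from .simulate import trajectory_class

log = logging.getLogger(__name__)

TRAJECTORY_CLASSES = (
    "stable-ancestral",
    "ancestral-gain",
    "ancestral-loss",
    "novel-low",
    "novel-gain",
    "absent",
)


def classify_trajectories(
    psi_values: pd.DataFrame,
    presence: pd.DataFrame,
    metadata: pd.DataFrame,
    radiations: tuple = ("LV", "LM", "LT"),
    nr: str = "NR",
    dsg_isoforms: set | None = None,
    threshold: float = 0.2,
) -> pd.DataFrame:
    """Classify each isoform's PSI trajectory per radiation.

    Parameters
    ----------
    psi_values
        isoform x sample PSI matrix (NaN where the gene is silent).
    presence
        isoform x clade boolean presence table (clade-level).
    dsg_isoforms
        optional restriction to isoforms of differentially spliced genes.

    Returns a long DataFrame with one row per (isoform, radiation).
    """
    for col in radiations + (nr,):
        if col not in presence.columns:
            raise FormatError(f"presence table lacks clade column {col!r}")
    rows = psi_values.index
    if dsg_isoforms is not None:
        rows = rows.intersection(sorted(dsg_isoforms))
    psi_values = psi_values.loc[rows]
    presence = presence.reindex(rows).fillna(False)

    clade_of = metadata["clade"]
    means = {}
    for clade in radiations + (nr,):
        samples = clade_of.index[clade_of == clade].intersection(
            psi_values.columns
        )
        if len(samples) == 0:
            raise FormatError(f"no samples for clade {clade!r}")
        with np.errstate(invalid="ignore"):
            means[clade] = np.nanmean(
                psi_values[samples].to_numpy(dtype=float), axis=1
            )

    absent_everywhere = ~presence[[nr, *radiations]].any(axis=1)
    if absent_everywhere.all() and len(rows):
        raise FormatError("all isoforms are absent everywhere")

    nr_present = presence[nr].to_numpy()
    nr_mean = np.where(nr_present, np.nan_to_num(means[nr]), 0.0)
    out = []
    for rad in radiations:
        rad_present = presence[rad].to_numpy()
        rad_mean = np.where(rad_present, np.nan_to_num(means[rad]), 0.0)
        delta = rad_mean - nr_mean
        classes = [
            trajectory_class(bool(pn), bool(pr), float(d), threshold)
            for pn, pr, d in zip(nr_present, rad_present, delta)
        ]
        out.append(
            pd.DataFrame(
                {
                    "isoform_id": rows,
                    "radiation": rad,
                    "class": classes,
                    "mean_psi_nr": np.where(nr_present, nr_mean, 0.0),
                    "mean_psi_radiation": rad_mean,
                    "delta_psi": delta,
                    "presence_nr": nr_present,
                    "presence_radiation": rad_present,
                }
            )
        )
    return pd.concat(out, ignore_index=True)


def class_counts(trajectories: pd.DataFrame) -> pd.DataFrame:
    """Per-radiation counts of each trajectory class."""
    return (
        trajectories.groupby(["radiation", "class"])
        .size()
        .unstack(fill_value=0)
        .reindex(columns=list(TRAJECTORY_CLASSES), fill_value=0)
    )


def count_novel_isoforms(
    presence_radiations: pd.DataFrame,
    presence_nr_species: pd.DataFrame,
    radiations: tuple = ("LV", "LM", "LT"),
) -> dict:
    """Count putatively novel isoforms.

    Novel = absent in *every* nonradiating species individually (an isoform
    present in even one NR species is ancestral) and present in at least
    one radiation.

    Parameters
    ----------
    presence_radiations
        isoform x radiation boolean presence (clade-level).
    presence_nr_species
        isoform x NR-species boolean presence (species-level, one column
        per nonradiating species).

    Returns
    -------
    dict with ``total``, per-radiation counts, and the novel flags Series.
    """
    for col in radiations:
        if col not in presence_radiations.columns:
            raise FormatError(f"presence table lacks radiation {col!r}")
    common = presence_radiations.index
    nr = presence_nr_species.reindex(common).fillna(False)
    in_any_nr = nr.any(axis=1)
    in_any_rad = presence_radiations[list(radiations)].any(axis=1)
    novel = ~in_any_nr & in_any_rad
    out: dict = {
        "total": int(novel.sum()),
        "novel": novel,
    }
    for rad in radiations:
        out[rad] = int((novel & presence_radiations[rad]).sum())
    return out
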