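"""Population-level derived statistics.

S-phase (EdU) fractions and their Dox/no-Dox fold changes normalized to a
parental reference, the coculture proportion-response relation, and the
shed-protein significance/fold-change filter used to nominate
sheddase-dependent supernatant proteins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from mapkdyn.errors import MapkdynError, ParameterError

__all__ = [
    "EdUObservation",
    "ShedProteinRecord",
    "sphase_fraction",
    "proliferation_fold_change",
    "edu_fold_table",
    "proportion_response_curve",
    "shed_records_from_abundance",
    "filter_shed_proteins",
]


@dataclass(frozen=True)
class EdUObservation:
    """EdU counts for one position/population/Dox state."""

    position: str
    condition: str
    population: str  # inducible | neighbor | parental
    n_nuclei: int
    n_edu_positive: int
    dox: bool

    def __post_init__(self) -> None:
        if self.n_nuclei <= 0:
            raise ParameterError("n_nuclei must be > 0")
        if not 0 <= self.n_edu_positive <= self.n_nuclei:
            raise ParameterError("n_edu_positive must lie in [0, n_nuclei]")


@dataclass(frozen=True)
class ShedProteinRecord:
    """Natural-log fold changes and p-values for one supernatant protein."""

    protein: str
    ln_fc_dox: float  # +Dox vs -Dox (WT)
    ln_fc_ko: float   # WT vs KO (+Dox)
    p_dox: float
    p_ko: float

    def __post_init__(self) -> None:
        for p in (self.p_dox, self.p_ko):
            if not 0.0 <= p <= 1.0:
                raise ParameterError("p-values must lie in [0, 1]")


def sphase_fraction(obs: EdUObservation) -> float:
    """Fraction of EdU-positive (S-phase) nuclei."""
    return obs.n_edu_positive / obs.n_nuclei


def proliferation_fold_change(
    dox_obs: EdUObservation,
    nodox_obs: EdUObservation,
    parental_folds=None,
) -> float:
    """+Dox over -Dox S-phase fraction, optionally parental-normalized.

    fold = fraction(+Dox) / fraction(-Dox); when ``parental_folds`` (raw
    folds of the parental condition) is given the fold is divided by their
    mean, so the parental condition normalized against itself has mean
    exactly 1 — the dashed line of the condition plots. A zero no-Dox
    fraction makes the fold undefined (NaN).
    """
    f0 = sphase_fraction(nodox_obs)
    if f0 == 0:
        return float("nan")
    fold = sphase_fraction(dox_obs) / f0
    if parental_folds is not None:
        parental_folds = np.asarray(list(parental_folds), float)
        if parental_folds.size == 0:
            raise MapkdynError("empty parental reference")
        fold /= float(np.mean(parental_folds))
    return fold


def edu_fold_table(
    table: pd.DataFrame,
    population: str,
    parental_population: str | None = "parental",
) -> pd.DataFrame:
    """Per-position +Dox/-Dox fold changes for one population.

    ``table`` uses the EdU CSV schema (position, condition, population,
    dox, n_nuclei, n_edu_positive). Returns one row per position with raw
    and parental-normalized folds (the latter only when the parental
    population is present in the table).
    """
    def _folds(pop):
        folds = {}
        sub = table[table["population"] == pop]
        for pos, grp in sub.groupby("position"):
            on = grp[grp["dox"]]
            off = grp[~grp["dox"]]
            if on.empty or off.empty:
                continue
            f_on = on["n_edu_positive"].sum() / on["n_nuclei"].sum()
            f_off = off["n_edu_positive"].sum() / off["n_nuclei"].sum()
            folds[pos] = f_on / f_off if f_off > 0 else float("nan")
        return folds

    folds = _folds(population)
    rows = [{"position": k, "fold": v} for k, v in sorted(folds.items())]
    df = pd.DataFrame(rows, columns=["position", "fold"])
    if parental_population is not None and \
            (table["population"] == parental_population).any():
        pf = np.array([v for v in _folds(parental_population).values()
                       if np.isfinite(v)])
        if pf.size == 0:
            raise MapkdynError("no finite parental folds")
        df["normalized_fold"] = df["fold"] / pf.mean()
    return df


def proportion_response_curve(table: pd.DataFrame) -> pd.DataFrame:
    """Neighbor S-phase fold change versus percent inducible cells.

    One row per position: percent = 100 x inducible nuclei / total nuclei
    (from the -Dox rows, i.e. plating composition), fold = neighbor
    +Dox/-Dox S-phase fold at that position.
    """
    rows = []
    for pos, grp in table.groupby("position"):
        comp = grp[~grp["dox"]]
        total = comp["n_nuclei"].sum()
        ind = comp.loc[comp["population"] == "inducible", "n_nuclei"].sum()
        percent = 100.0 * ind / total if total else 0.0
        nb = grp[grp["population"] == "neighbor"]
        on, off = nb[nb["dox"]], nb[~nb["dox"]]
        if on.empty or off.empty:
            continue
        f_on = on["n_edu_positive"].sum() / on["n_nuclei"].sum()
        f_off = off["n_edu_positive"].sum() / off["n_nuclei"].sum()
        fold = f_on / f_off if f_off > 0 else float("nan")
        rows.append({"position": pos, "percent_inducible": percent, "fold": fold})
    return pd.DataFrame(rows, columns=["position", "percent_inducible", "fold"])


def shed_records_from_abundance(table: pd.DataFrame) -> list[ShedProteinRecord]:
    """Fold changes and p-values from a replicate abundance table.

    For each protein, ln fold changes are differences of mean
    log-abundance: +Dox vs -Dox within WT, and WT vs KO within +Dox;
    p-values come from unpaired two-sample t-tests across replicates on the
    log scale.
    """
    records = []
    for pid, grp in table.groupby("protein", sort=True):
        ln = np.log(grp["abundance"].to_numpy(float))
        wt_dox = ln[(grp["genotype"] == "WT") & grp["dox"]]
        wt_nod = ln[(grp["genotype"] == "WT") & ~grp["dox"]]
        ko_dox = ln[(grp["genotype"] == "KO") & grp["dox"]]
        _, p_dox = stats.ttest_ind(wt_dox, wt_nod)
        _, p_ko = stats.ttest_ind(wt_dox, ko_dox)
        records.append(ShedProteinRecord(
            protein=str(pid),
            ln_fc_dox=float(wt_dox.mean() - wt_nod.mean()),
            ln_fc_ko=float(wt_dox.mean() - ko_dox.mean()),
            p_dox=float(p_dox),
            p_ko=float(p_ko),
        ))
    return records


def filter_shed_proteins(
    records,
    p_max: float = 0.05,
    fc_min: float = 1.5,
) -> pd.DataFrame:
    """Significance + fold-change filter for shed-protein candidates.

    Retains proteins significant (p < p_max) in both the +Dox vs -Dox and
    WT vs KO comparisons; a retained protein is "in box" iff both |ln FC|
    exceed ln(fc_min) (the grey >1.5-fold boxes of the scatter plots).
    Output is ranked by ln_fc_dox descending. Monotone: relaxing p_max or
    fc_min never removes a retained protein.
    """
    ln_min = np.log(fc_min)
    rows = []
    for r in records:
        if r.p_dox < p_max and r.p_ko < p_max:
            rows.append({
                "protein": r.protein,
                "ln_fc_dox": r.ln_fc_dox,
                "ln_fc_ko": r.ln_fc_ko,
                "p_dox": r.p_dox,
                "p_ko": r.p_ko,
                "in_box": abs(r.ln_fc_dox) > ln_min and abs(r.ln_fc_ko) > ln_min,
            })
    df = pd.DataFrame(rows, columns=[
        "protein", "ln_fc_dox", "ln_fc_ko", "p_dox", "p_ko", "in_box",
    ])
    df["in_box"] = df["in_box"].astype(bool)
    return df.sort_values("ln_fc_dox", ascending=False).reset_index(drop=True)
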