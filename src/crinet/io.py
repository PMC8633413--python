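"""Tabular I/O with strict schema validation.

Formats:

* genotypes (CSV): ``marker_id, chromosome, position, segregation`` then one
  column per individual; codes 0/1 (testcross) or 0/1/2 (intercross), NA for
  missing.
* phenotypes (long CSV): ``individual, trait, time, value`` with trait in
  {height, diameter}; the design must be balanced (every individual measured
  for both traits at every time point).
* effect curves (wide CSV): ``snp_id, trait`` then one column per time point.
* mapping results (TSV), network edge lists (CSV) and GraphML.

Writers emit rows in deterministic order; readers fail with the offending
line numbers.
"""

from __future__ import annotations

import json

import networkx as nx
import numpy as np
import pandas as pd

from .errors import SchemaError
from .growth import CRIParams
from .mapping import MarkerGenotypes, PhenotypeSet, _N_CLASSES

_GENO_META = ["marker_id", "chromosome", "position", "segregation"]
_TRAITS = ("height", "diameter")


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def read_genotypes(path) -> tuple:
    """Read a genotype table; returns ``(markers, individuals)``."""
    df = pd.read_csv(path, dtype={"marker_id": str, "chromosome": str})
    missing = [c for c in _GENO_META if c not in df.columns]
    if missing:
        raise SchemaError(f"genotype file missing columns {missing}")
    individuals = [c for c in df.columns if c not in _GENO_META]
    if not individuals:
        raise SchemaError("genotype file has no individual columns")
    markers = []
    for idx, row in df.iterrows():
        seg = row["segregation"]
        if seg not in _N_CLASSES:
            raise SchemaError(
                f"line {idx + 2}: unknown segregation {seg!r}; expected one of "
                f"{sorted(_N_CLASSES)}")
        vals = row[individuals]
        codes = np.full(len(individuals), -1, dtype=np.int64)
        for i, v in enumerate(vals):
            if pd.isna(v):
                continue
            try:
                codes[i] = int(v)
            except (TypeError, ValueError):
                raise SchemaError(
                    f"line {idx + 2}: genotype code {v!r} is not an integer")
        try:
            markers.append(MarkerGenotypes(
                marker_id=str(row["marker_id"]), segregation=seg, codes=codes,
                chromosome=None if pd.isna(row["chromosome"]) else str(row["chromosome"]),
                position=None if pd.isna(row["position"]) else float(row["position"])))
        except Exception as e:
            raise SchemaError(f"line {idx + 2}: {e}") from e
    return markers, individuals


def write_genotypes(markers, individuals, path) -> None:
    rows = []
    for m in markers:
        row = {"marker_id": m.marker_id, "chromosome": m.chromosome,
               "position": m.position, "segregation": m.segregation}
        for ind, c in zip(individuals, m.codes):
            row[ind] = "" if c < 0 else int(c)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def read_phenotypes(path) -> PhenotypeSet:
    df = pd.read_csv(path)
    need = ["individual", "trait", "time", "value"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise SchemaError(f"phenotype file missing columns {missing}")
    bad_trait = df.index[~df["trait"].isin(_TRAITS)]
    if len(bad_trait):
        raise SchemaError(
            f"line {bad_trait[0] + 2}: trait must be one of {_TRAITS}")
    bad_val = df.index[~np.isfinite(pd.to_numeric(df["value"], errors="coerce"))]
    if len(bad_val):
        raise SchemaError(f"line {bad_val[0] + 2}: non-numeric phenotype value")
    times = np.sort(df["time"].unique().astype(float))
    individuals = list(dict.fromkeys(df["individual"].astype(str)))
    n, T = len(individuals), times.size
    arrays = {tr: np.full((n, T), np.nan) for tr in _TRAITS}
    tidx = {t: k for k, t in enumerate(times)}
    iidx = {ind: k for k, ind in enumerate(individuals)}
    for _, row in df.iterrows():
        arrays[row["trait"]][iidx[str(row["individual"])],
                             tidx[float(row["time"])]] = float(row["value"])
    for tr in _TRAITS:
        if np.isnan(arrays[tr]).any():
            i, t = np.argwhere(np.isnan(arrays[tr]))[0]
            raise SchemaError(
                f"unbalanced design: individual {individuals[i]!r} is missing "
                f"{tr} at time {times[t]:g} (a common time grid is required)")
    return PhenotypeSet(individuals=individuals, times=times,
                        heights=arrays["height"], diameters=arrays["diameter"])


def write_phenotypes(phen: PhenotypeSet, path) -> None:
    from .simulate import phenotypes_to_long
    phenotypes_to_long(phen).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# mapping results and effect curves
# ---------------------------------------------------------------------------

def write_mapping_results(results, path) -> None:
    rows = []
    for r in results:
        row = {"marker_id": r.marker_id, "chromosome": r.chromosome,
               "position": r.position, "lrt": r.lrt, "df": r.df,
               "p_value": r.p_value, "p_fdr": r.p_fdr,
               "significant": r.significant, "n_used": r.n_used,
               "failed": r.failed}
        if r.subtest_independent is not None:
            row["lrt_independent"] = r.subtest_independent.lrt
            row["p_independent"] = r.subtest_independent.p_value
        if r.subtest_interaction is not None:
            row["lrt_interaction"] = r.subtest_interaction.lrt
            row["p_interaction"] = r.subtest_interaction.p_value
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_mapping_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_effect_curves(pairs, path) -> None:
    """Wide CSV of effect curves: one row per (snp, trait)."""
    rows = []
    for pair in pairs:
        cols = {f"t{t:g}": v for t, v in zip(pair.times, pair.g1)}
        rows.append({"snp_id": pair.marker_id, "trait": "height", **cols})
        cols = {f"t{t:g}": v for t, v in zip(pair.times, pair.g2)}
        rows.append({"snp_id": pair.marker_id, "trait": "diameter", **cols})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_effect_curves(path) -> tuple:
    """Read the wide effect-curve CSV; returns ``(curves, snp_ids, times)``
    with curves (p, 2T), height block first."""
    df = pd.read_csv(path)
    if "snp_id" not in df.columns or "trait" not in df.columns:
        raise SchemaError("effect-curve file needs snp_id and trait columns")
    tcols = [c for c in df.columns if c.startswith("t")
             and c not in ("trait", "snp_id")]
    times = np.array([float(c[1:]) for c in tcols])
    ids = list(dict.fromkeys(df["snp_id"].astype(str)))
    curves = np.full((len(ids), 2 * times.size), np.nan)
    for k, sid in enumerate(ids):
        sub = df[df["snp_id"].astype(str) == sid]
        for _, row in sub.iterrows():
            block = 0 if row["trait"] == "height" else 1
            curves[k, block * times.size:(block + 1) * times.size] = \
                row[tcols].to_numpy(dtype=float)
    if np.isnan(curves).any():
        raise SchemaError("effect-curve file is missing trait rows")
    return curves, ids, times


# ---------------------------------------------------------------------------
# networks and parameters
# ---------------------------------------------------------------------------

def write_network(net, csv_path, graphml_path=None) -> None:
    rows = [{"source": u, "target": v, "trait": net.trait,
             "variant": net.variant, "layer": net.layer,
             "sign": d["sign"], "weight": d["weight"]}
            for u, v, d in sorted(net.graph.edges(data=True))]
    pd.DataFrame(rows, columns=["source", "target", "trait", "variant",
                                "layer", "sign", "weight"]).to_csv(
        csv_path, index=False)
    if graphml_path is not None:
        nx.write_graphml(net.graph, graphml_path)


def write_cri_params(params: CRIParams, path) -> None:
    with open(path, "w") as fh:
        json.dump(params.to_dict(), fh, indent=2)


def read_cri_params(path) -> CRIParams:
    with open(path) as fh:
        return CRIParams(**json.load(fh))
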