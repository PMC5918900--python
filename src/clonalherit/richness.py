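"""OTU richness tables and linear mixed models for the clonal network.

Two models mirror the study design. The mother-vs-daughter contrast fits
richness on ramet role with a random intercept per ecotype. The dilution
model, restricted to daughter ramets, fits richness on position along the
stolon (D1 vs D2) and stolon order (1st vs 2nd emitted), with random
intercepts for ecotype and for stolon-within-ecotype.

F statistics for the 1-df fixed effects are squared Wald t ratios, with
denominator degrees of freedom from the containment method: an effect varying
at a given level of the grouping hierarchy is tested against the number of
units at that level minus the units of the coarser level minus the fixed
parameters estimated at that level. Residual normality is checked
(Shapiro-Wilk) and the response is log(x+1)- or sqrt-transformed when needed;
the transformation actually used is always reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

from .dataset import OtuDataset

TRANSFORMS = {
    "none": lambda x: x,
    "log": lambda x: np.log1p(x),
    "sqrt": lambda x: np.sqrt(x),
}


@dataclass
class EffectTest:
    term: str
    estimate: float
    se: float
    f_stat: float
    df_num: int
    df_den: int
    p_value: float


@dataclass
class MixedModelResult:
    formula: str
    effects: list[EffectTest]
    random_variances: dict
    transformation: str
    shapiro_p: float | None
    n_obs: int
    converged: bool

    def effect(self, term: str) -> EffectTest:
        for e in self.effects:
            if e.term == term:
                return e
        raise KeyError(term)


def richness_table(ds: OtuDataset, by_phylum: bool = False,
                   roles: tuple[str, ...] = ("mother_root", "daughter_root")) -> pd.DataFrame:
    """One row per sample (x phylum if requested) with the number of OTUs
    present (count > 0) in scope. Internode and control samples are excluded
    by default."""
    keep = ds.samples.index[ds.samples["role"].isin(roles)]
    counts = ds.counts.loc[keep]
    meta = ds.samples.loc[keep]
    rows = []
    scopes: list[tuple[str, pd.Index]] = [("all", counts.columns)]
    if by_phylum:
        phyla = ds.taxonomy.loc[counts.columns, "phylum"].fillna("unknown")
        for ph in sorted(phyla.unique()):
            scopes.append((ph, counts.columns[(phyla == ph).to_numpy()]))
    present = counts > 0
    for sid in counts.index:
        m = meta.loc[sid]
        for scope, cols in scopes:
            rows.append({
                "sample_id": sid,
                "ecotype": m["ecotype"], "role": m["role"], "position": m["position"],
                "stolon": m["stolon"], "marker": m["marker"],
                "taxon_scope": scope,
                "richness": int(present.loc[sid, cols].sum()),
            })
    return pd.DataFrame(rows)


def _fit_lmm(data: pd.DataFrame, formula: str, vc_formula: dict | None = None):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data, groups=data["ecotype"],
                            re_formula="1", vc_formula=vc_formula)
        last_exc = None
        for method in ("lbfgs", "bfgs", "powell", "nm"):
            try:  # near-boundary variance can break individual optimizers
                return model.fit(reml=True, method=method)
            except np.linalg.LinAlgError as exc:
                last_exc = exc
        raise last_exc


def _wald_f(fit, term: str, df_den: int) -> EffectTest:
    est = float(fit.fe_params[term])
    se = float(fit.bse_fe[term])
    f = (est / se) ** 2
    p = float(stats.f.sf(f, 1, df_den))
    return EffectTest(term, est, se, f, 1, df_den, p)


def _choose_transform(data: pd.DataFrame, formula: str, vc_formula: dict | None,
                      alpha: float = 0.05):
    """Fit untransformed; fall back to log(x+1) then sqrt when the residuals
    fail a Shapiro-Wilk normality check."""
    last = None
    for name in ("none", "log", "sqrt"):
        d = data.copy()
        d["y"] = TRANSFORMS[name](d["richness"].astype(float))
        fit = _fit_lmm(d, "y ~ " + formula, vc_formula)
        resid = np.asarray(fit.resid, dtype=float)
        sh_p = float(stats.shapiro(resid).pvalue) if 3 <= len(resid) <= 5000 else None
        last = (name, fit, sh_p)
        if sh_p is None or sh_p >= alpha:
            return last
    return last  # none passed; report the sqrt fit with its diagnostic


def fit_mother_daughter(rt: pd.DataFrame) -> MixedModelResult:
    """Mixed model of richness on ramet role (mother vs daughter), random
    intercept per ecotype."""
    data = rt
    if "taxon_scope" in data.columns and data["taxon_scope"].nunique() > 1:
        data = data[data["taxon_scope"] == "all"]
    data = data[data["role"].isin(["mother_root", "daughter_root"])].copy()
    if data["role"].nunique() < 2:
        raise ValueError("need both mother and daughter samples")
    if data.groupby("ecotype")["role"].nunique().ge(2).sum() < 2:
        raise ValueError("need >=2 ecotypes with both roles")
    data["role"] = pd.Categorical(data["role"], ["daughter_root", "mother_root"])
    name, fit, sh_p = _choose_transform(data, "C(role)", None)
    n, g = len(data), data["ecotype"].nunique()
    ddf = n - g - 1  # containment: role varies within ecotype
    eff = _wald_f(fit, "C(role)[T.mother_root]", ddf)
    eff.term = "role[mother_root]"
    return MixedModelResult("richness ~ role + (1|ecotype)", [eff],
                            {"ecotype": float(fit.cov_re.iloc[0, 0])},
                            name, sh_p, n, bool(fit.converged))


def fit_dilution(rt: pd.DataFrame) -> MixedModelResult:
    """Daughters-only mixed model: richness ~ position + stolon with random
    intercepts for ecotype and stolon-within-ecotype.

    Negative position estimates mean D2 poorer than D1; negative stolon
    estimates mean the 2nd stolon poorer than the 1st.
    """
    data = rt[rt["role"] == "daughter_root"].copy()
    if "taxon_scope" in data.columns:
        data = data[data["taxon_scope"] == "all"]
    if data["position"].nunique() < 2 or data["stolon"].nunique() < 2:
        raise ValueError("need both positions and both stolons among daughters")
    data["position"] = pd.Categorical(data["position"], ["D1", "D2"])
    data["stolon"] = pd.Categorical(data["stolon"].astype(int), [1, 2])
    vc = {"stolon_unit": "0 + C(stolon)"}
    name, fit, sh_p = _choose_transform(data, "C(position) + C(stolon)", vc)
    n, g = len(data), data["ecotype"].nunique()
    units = data.groupby(["ecotype", "stolon"], observed=True).ngroups
    eff_pos = _wald_f(fit, "C(position)[T.D2]", n - units - 1)
    eff_pos.term = "position[D2]"
    eff_sto = _wald_f(fit, "C(stolon)[T.2]", units - g - 1)
    eff_sto.term = "stolon[2]"
    rand = {"ecotype": float(fit.cov_re.iloc[0, 0]),
            "stolon_within_ecotype": float(fit.vcomp[0]) if len(fit.vcomp) else 0.0}
    return MixedModelResult("richness ~ position + stolon + (1|ecotype/stolon)",
                            [eff_pos, eff_sto], rand, name, sh_p, n, bool(fit.converged))


def phylum_models(rt: pd.DataFrame, min_ecotypes: int = 3) -> dict[str, MixedModelResult | str]:
    """Mother-vs-daughter model per phylum; phyla observed (nonzero richness
    in both roles) in fewer than ``min_ecotypes`` ecotypes are skipped with a
    report entry instead of an unstable fit."""
    out: dict[str, MixedModelResult | str] = {}
    for ph, sub in rt[rt["taxon_scope"] != "all"].groupby("taxon_scope"):
        ok_ecos = 0
        for _, eco_rows in sub.groupby("ecotype"):
            by_role = eco_rows.groupby("role")["richness"].max()
            if by_role.get("mother_root", 0) > 0 and by_role.get("daughter_root", 0) > 0:
                ok_ecos += 1
        if ok_ecos < min_ecotypes:
            out[ph] = f"skipped: nonzero in both roles for only {ok_ecos} ecotypes"
            continue
        try:
            out[ph] = fit_mother_daughter(sub)
        except Exception as exc:
            out[ph] = f"skipped: {exc}"
    return out
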