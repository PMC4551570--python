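"""Text and JSON rendering of agreement reports.

The text report mirrors the five-table layout conventional in
method-comparison studies: between-method bias, inter-method
(between-subject) agreement, intra-method (within-subject) agreement,
overall agreement, and the mixed-effects overall correlation, followed
by the interchangeability verdict.  Variances are printed in squared
data units with companion standard deviations in data units.

The JSON document is schema-versioned and carries every estimate,
deviance, df and p-value, so a stored report can be re-loaded and the
decision re-applied without refitting.
"""

from __future__ import annotations

import json
import math

import numpy as np

from .inference import AgreementReport, BiasResult, LrtResult, Verdict

SCHEMA_VERSION = "1.0"

_TABLE_HEADINGS = (
    "Between-method bias",
    "Inter-method agreement",
    "Intra-method agreement",
    "Overall agreement",
    "Estimated overall correlation",
)


def _fmt_p(p: float) -> str:
    return f"{p:.4g}" if p >= 1e-4 else f"{p:.4e}"


def _var_table(title, vars_pair, p_value, labels):
    v1, v2 = vars_pair
    lines = [
        title,
        "-" * len(title),
        f"{'':14s}{labels[0]:>14s}{labels[1]:>14s}",
        f"{'variance (units^2)':<22s}{v1:>10.4f}{v2:>14.4f}",
        f"{'SD (units)':<22s}{math.sqrt(max(v1, 0)):>10.4f}"
        f"{math.sqrt(max(v2, 0)):>14.4f}",
        f"p-value: {_fmt_p(p_value)}",
        "",
    ]
    return lines


def render_text(
    report: AgreementReport,
    verdict: Verdict | None = None,
    labels: tuple[str, str] = ("method 1", "method 2"),
) -> str:
    """Five labeled tables plus (optionally) the verdict."""
    b = report.bias
    lines = [
        _TABLE_HEADINGS[0],
        "-" * len(_TABLE_HEADINGS[0]),
        f"bias (units): {b.estimate:.4f}   SE: {b.se:.4f}   "
        f"t = {b.t_stat:.3f} on df = {b.df:.1f} ({b.df_method})",
        f"p-value: {_fmt_p(b.p_value)}",
        "",
    ]
    lines += _var_table(
        _TABLE_HEADINGS[1], report.between_vars, report.between_test.p_value, labels
    )
    lines += _var_table(
        _TABLE_HEADINGS[2], report.within_vars, report.within_test.p_value, labels
    )
    lines += _var_table(
        _TABLE_HEADINGS[3], report.overall_vars, report.overall_test.p_value, labels
    )
    lines += [
        _TABLE_HEADINGS[4],
        "-" * len(_TABLE_HEADINGS[4]),
        f"correlation coefficient: {report.overall_correlation:.4f}",
        "",
    ]
    if report.failures:
        lines.append(f"WARNING: non-converged fits: {', '.join(report.failures)}")
        lines.append("")
    if verdict is not None:
        lines += [
            "Verdict",
            "-------",
            "interchangeable" if verdict.interchangeable
            else f"NOT interchangeable; preferred method: {verdict.preferred_method} "
                 f"({labels[verdict.preferred_method - 1]})",
            verdict.rationale,
            "",
        ]
    return "\n".join(lines)


def _lrt_dict(t: LrtResult) -> dict:
    return {
        "stat": t.stat,
        "df": t.df,
        "p_value": t.p_value,
        "deviance_full": t.deviance_full,
        "deviance_reduced": t.deviance_reduced,
        "spec_full": str(t.spec_full) if t.spec_full else None,
        "spec_reduced": str(t.spec_reduced) if t.spec_reduced else None,
    }


def report_to_dict(
    report: AgreementReport,
    verdict: Verdict | None = None,
    config: dict | None = None,
) -> dict:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "bias": {
            "estimate": report.bias.estimate,
            "se": report.bias.se,
            "df": report.bias.df,
            "t_stat": report.bias.t_stat,
            "p_value": report.bias.p_value,
            "df_method": report.bias.df_method,
        },
        "between_test": _lrt_dict(report.between_test),
        "within_test": _lrt_dict(report.within_test),
        "overall_test": _lrt_dict(report.overall_test),
        "between_vars": list(report.between_vars),
        "within_vars": list(report.within_vars),
        "overall_vars": list(report.overall_vars),
        "overall_correlation": report.overall_correlation,
        "failures": list(report.failures),
    }
    if verdict is not None:
        doc["verdict"] = {
            "interchangeable": verdict.interchangeable,
            "failed_criteria": list(verdict.failed_criteria),
            "preferred_method": verdict.preferred_method,
            "rationale": verdict.rationale,
        }
    if config is not None:
        doc["config"] = config
    return doc


def _lrt_from_dict(d: dict) -> LrtResult:
    from .model import ModelSpec

    def spec(s):
        if not s:
            return None
        a, b = s.strip("()").split(",")
        return ModelSpec(a, b)

    return LrtResult(
        stat=d["stat"], df=d["df"], p_value=d["p_value"],
        deviance_full=d.get("deviance_full"),
        deviance_reduced=d.get("deviance_reduced"),
        spec_full=spec(d.get("spec_full")),
        spec_reduced=spec(d.get("spec_reduced")),
    )


def report_from_dict(doc: dict) -> AgreementReport:
    """Rebuild a numbers-only report (no fit objects) from a JSON doc."""
    b = doc["bias"]
    return AgreementReport(
        bias=BiasResult(
            estimate=b["estimate"], se=b["se"], df=b["df"],
            t_stat=b["t_stat"], p_value=b["p_value"],
            df_method=b.get("df_method", "satterthwaite"),
        ),
        between_test=_lrt_from_dict(doc["between_test"]),
        within_test=_lrt_from_dict(doc["within_test"]),
        overall_test=_lrt_from_dict(doc["overall_test"]),
        between_vars=tuple(doc["between_vars"]),
        within_vars=tuple(doc["within_vars"]),
        overall_vars=tuple(doc["overall_vars"]),
        overall_correlation=doc["overall_correlation"],
        failures=list(doc.get("failures", [])),
    )


def render_report(
    report: AgreementReport,
    verdict: Verdict | None = None,
    fmt: str = "text",
    labels: tuple[str, str] = ("method 1", "method 2"),
    config: dict | None = None,
) -> str:
    """Render a report as human-readable text or machine-readable JSON."""
    if fmt == "text":
        return render_text(report, verdict, labels)
    if fmt == "json":
        return json.dumps(report_to_dict(report, verdict, config), indent=2)
    raise ValueError(f"unknown format {fmt!r}")


def results_summary(res) -> str:
    """Compact summary table for a single model fit."""
    D, S = res.D_hat, res.Sigma_hat
    om = res.omega
    lines = [
        f"Two-method replicated LME fit, structure {res.spec}",
        f"subjects: {res.n_subjects}   observations: {res.n_obs_total}   "
        f"converged: {res.converged}",
        f"-2 log likelihood: {res.minus2loglik:.4f}   "
        f"covariance parameters: {res.n_cov_params}",
        "",
        f"method means (units): mu1 = {res.mu[0]:.4f} "
        f"(SE {math.sqrt(res.fixed_cov[0, 0]):.4f}), "
        f"mu2 = {res.mu[1]:.4f} (SE {math.sqrt(res.fixed_cov[1, 1]):.4f})",
        "",
        "covariance estimates (units^2):",
        f"  between-subject D:     [[{D[0,0]:.4f}, {D[0,1]:.4f}], "
        f"[{D[1,0]:.4f}, {D[1,1]:.4f}]]",
        f"  within-subject Sigma:  [[{S[0,0]:.4f}, {S[0,1]:.4f}], "
        f"[{S[1,0]:.4f}, {S[1,1]:.4f}]]",
        f"  overall D + Sigma:     [[{om[0,0]:.4f}, {om[0,1]:.4f}], "
        f"[{om[1,0]:.4f}, {om[1,1]:.4f}]]",
        f"  overall correlation:   {res.overall_correlation:.4f}",
    ]
    return "\n".join(lines)
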