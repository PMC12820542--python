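"""Egger regression and trim-and-fill on the packaged 77-study table."""

from metaweight import egger_test, load_pe_bi_effects, pool_random, trim_and_fill

effects = load_pe_bi_effects()

egger = egger_test(effects)
print("Egger regression (SND on precision, unweighted OLS)")
print(
    f"  intercept {egger.intercept:.3f} (SE {egger.intercept_se:.3f}, "
    f"t {egger.t_intercept:.3f}, df {egger.df}, p {egger.p_intercept:.2f})"
)
print(
    f"  slope     {egger.slope:.3f} (SE {egger.slope_se:.3f}, "
    f"t {egger.t_slope:.3f}, p {egger.p_slope:.2g})"
)
print(f"  asymmetry flagged at p<.10: {egger.asymmetric}")

unadjusted = pool_random(effects).r
tf_default = trim_and_fill(effects)  # L0 moment estimator
tf_run = trim_and_fill(effects, side="right", estimator="R0")
print("\nTrim-and-fill")
print(f"  unadjusted pooled r       : {unadjusted:.3f}")
print(f"  L0 estimator: k0 = {tf_default.k0} (no studies imputed)")
print(
    f"  R0 estimator, right flank : k0 = {tf_run.k0}, "
    f"adjusted r = {tf_run.adjusted.r:.3f}"
)
print(
    "\nThe nonsignificant intercept means no strong evidence of small-study"
    "\nbias; the significant slope reflects genuine heterogeneity. The two"
    "\ntrim-and-fill estimators disagree about missing studies — the"
    "\nrun-based R0 imputes left-flank studies and shrinks the estimate."
)
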