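"""The likelihood-ratio alternative to thresholding.

The observed t statistic is weighed under H1 (a shift of delta on the t
scale, at the minimum effect size of interest) against H0; the ratio
multiplies the prior odds.  No dichotomization: both replicas simply
move the posterior up, by different amounts.
"""

from flexpst import (
    REPLICAS,
    WEIGHTS,
    geometry_from_summaries,
    likelihood_ratio,
    posterior_update,
    welch_t,
)

for name, (placebo, treatment) in REPLICAS.items():
    res = welch_t(placebo, treatment)
    geom = geometry_from_summaries(placebo, treatment, WEIGHTS)
    lr = likelihood_ratio(res.t, geom, method="shifted")
    lr_nct = likelihood_ratio(res.t, geom, method="noncentral")
    post = posterior_update(lr, WEIGHTS.pr)
    print(f"{name}: t = {res.t:.3f}, LR = {lr:.1f} "
          f"(noncentral-t variant: {lr_nct:.1f})")
    print(f"  prior {WEIGHTS.pr:.2f} -> posterior odds {post.posterior_odds:.1f} "
          f"-> posterior P(H1) = {post.posterior_prob:.3f}")

print("\nStarting from 50:50, the first replica leaves the drug ~39x more")
print("likely effective than not (P ~ 0.97); the second ~6x (P ~ 0.86).")
print("Both replicas agree the drug is probably effective — the conflict")
print("created by thresholding disappears.")
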