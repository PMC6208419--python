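"""The kinetic model family and its derived quantities.

Evaluates each closed-form curve at the three clinical imaging times and
derives half-life, peak, and 24-h exposure for a typical systemic profile.
"""

import numpy as np

from nanopk import (
    KineticParams,
    ModelVariant,
    auc_closed_form,
    eval_double_exp,
    eval_mono_decay,
    eval_uptake_only,
    half_life,
    time_of_peak,
)

times = np.array([0.5, 5.0, 24.0])  # hours post injection

# Intravenous systemic profile: first-order washout with ~7.8 h half-life.
k_out = np.log(2) / 7.83
iv = eval_mono_decay(A=2.5, k_out=k_out, t=times)
print("i.v. heart concentration (%ID/g) at", times, "h:", np.round(iv, 3))
print("  half-life     = %.2f h" % half_life(k_out))
print("  AUC(0-24 h)   = %.2f %%ID/g*h" % auc_closed_form(
    ModelVariant.MONO_DECAY, KineticParams(A=2.5, k_out=k_out)))

# Intraperitoneal profile: absorption phase then elimination.
p = KineticParams(A=2.3, k_in=0.6, k_out=np.log(2) / 7.48)
ip = eval_double_exp(p.A, p.k_in, p.k_out, times)
t_peak = time_of_peak(p.k_in, p.k_out)
print("\ni.p. heart concentration (%ID/g) at", times, "h:", np.round(ip, 3))
print("  peak at %.2f h, AUC(0-24 h) = %.2f %%ID/g*h"
      % (t_peak, auc_closed_form(ModelVariant.DOUBLE_EXP, p)))

# Sink-like organ (liver): saturating uptake, no elimination phase.
liver = eval_uptake_only(A=12.0, k_in=0.35, t=times)
print("\nliver concentration (%ID/g) at", times, "h:", np.round(liver, 3),
      "\n  (saturates toward 12 %ID/g; no half-life within the study window)")
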