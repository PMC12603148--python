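"""Generate a small synthetic airway-phantom cohort and inspect it.

Builds 3 FBA (obstructed) and 3 NFBA (control) chest-CT phantoms and
prints, per patient, the label, the obstruction site/length, and the
airway-mask volume. FBA masks are smaller because the airway distal to the
plug is truncated — the morphological signal the classifier must find.
"""

import numpy as np

from lucent.phantom import PhantomSpec, make_cohort

spec = PhantomSpec()  # 4 generations, 128 mm^3 volume at 1 mm spacing
records = make_cohort(n_fba=3, n_nfba=3, spec=spec, seed=42)

print(f"{'patient':>8} {'label':>6} {'mask mm^3':>10}  obstruction")
for rec in records:
    obs = ("segment %d, plug %.1f mm" % rec.obstruction) if rec.obstruction else "-"
    print(f"{rec.patient_id:>8} {rec.label:>6} {int(rec.mask.sum()):>10}  {obs}")

fba = np.mean([r.mask.sum() for r in records if r.label == "FBA"])
nfba = np.mean([r.mask.sum() for r in records if r.label == "NFBA"])
print(f"\nmean airway volume: FBA {fba:.0f} mm^3 < NFBA {nfba:.0f} mm^3 "
      "(distal truncation removes airway)")
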