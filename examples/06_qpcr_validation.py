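"""Validate copy-number calls with ΔΔCt qPCR math and the cv% gate.

qPCR copy number relative to a diploid single-copy reference locus:
ΔΔCt = (Ct_target - Ct_ref)_sample - (Ct_target - Ct_ref)_calibrator and
CN = 2 x 2^(-ΔΔCt) — each cycle of earlier amplification doubles dosage.
Two CN estimates of the same locus are concordant when their coefficient
of variation (|a-b| / (sqrt(2) x mean)) is below 0.25.
"""

from cnvpop import QpcrMeasurement, ddct_copy_number, cv_concordance

print("ΔΔCt -> copy number (calibrator is a known-diploid control):")
for ct_target, label in [(20.0, "same as calibrator"), (19.0, "1 cycle earlier"),
                         (21.0, "1 cycle later"), (18.0, "2 cycles earlier")]:
    m = QpcrMeasurement(sample_id="s", target_id="locus1",
                        ct_target=ct_target, ct_reference=20.0,
                        calibrator_ct_target=20.0, calibrator_ct_reference=20.0)
    print(f"  Ct_target={ct_target:5.1f} ({label:18s}) -> CN = {ddct_copy_number(m):.2f}")

print("\ncv% concordance gate between sequencing CN and qPCR CN:")
for a, b in [(2.0, 2.1), (2.0, 2.6), (1.0, 1.4), (2.0, 4.0)]:
    r = cv_concordance(a, b)
    verdict = "concordant" if r.acceptable else "discordant"
    print(f"  {a} vs {b}: cv = {r.cv:.3f} -> {verdict} (gate: cv < 0.25)")
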