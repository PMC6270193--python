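"""Recompute external-validation statistics from the packaged activity table.

The package ships a transcription of a published 37-compound betulinic
acid / betulin HT29 cytotoxicity series (26 training, 11 test compounds,
experimental and model-predicted pIC50s). This script recomputes PRESS,
RMSEP, r²pred and both R²m conventions from those numbers alone.
"""

from fragqsar import load_paper_tables, pic50_from_ic50, validation_report

records = [r for r in load_paper_tables() if not r.compound_id.startswith("ester-")]
report = validation_report(records)

print(f"training compounds : {report.n_train}")
print(f"test compounds     : {report.n_test}")
print(f"training mean pIC50: {report.train_mean:.3f}")
print(f"PRESS              : {report.press:.5f}   (sum of squared test residuals)")
print(f"RMSEP              : {report.rmsep:.3f}     (log units; published 0.201)")
print(f"r2_pred            : {report.r2_pred:.3f}     (published 0.675)")
print(f"R2m (observed axis): {report.r2_m_obs:.3f}")
print(f"R2m (predicted ax.): {report.r2_m_pred:.3f}")
print()
print("IC50 -> pIC50 for the prospectively synthesized betulin 28-O-esters:")
for name, ic50 in [("maleyl", 83.09), ("phthalyl", 35.33), ("hexahydrophthalyl", 30.05)]:
    print(f"  {name:18s} {ic50:6.2f} uM -> pIC50 {pic50_from_ic50(ic50):.3f}")
print("  censored '>100 uM'        -> pIC50", pic50_from_ic50(100, censored=True))
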