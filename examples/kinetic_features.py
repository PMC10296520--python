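"""Kinetic curve typing: percent enhancement ratios and their categories.

The two features are the percent signal change pre -> 1st post-contrast
(initial enhancement) and 1st -> 4th post-contrast (delayed phase); the
category pair (slow/medium/fast x persistent/plateau/washout) is the
standard clinical curve type — washout curves are the classic malignancy
flag, though small early lesions are often persistent.
"""

from dcefoci import TimeIntensityCurve, features_from_curve

curves = {
    "benign-looking focus": TimeIntensityCurve(se_pre=100, se_post1=140, se_post4=165),
    "indeterminate": TimeIntensityCurve(se_pre=100, se_post1=180, se_post4=185),
    "classic malignant": TimeIntensityCurve(se_pre=100, se_post1=250, se_post4=200),
}

for name, curve in curves.items():
    f = features_from_curve(curve)
    print(
        f"{name:22s} initial {f.initial_enhancement_pct:6.1f}% ({f.initial_category}), "
        f"delayed {f.delayed_phase_pct:6.1f}% ({f.delayed_category})"
    )

print()
print("A 150% initial rise with a -20% delayed drop is the (fast, washout)")
print("pattern; an early rise that keeps climbing (> +10%) is 'persistent'.")
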