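"""Published two-cultivar field-trial means used as worked-example inputs.

Each entry gives the printed replicate means of the test and reference
hybrid-rice cultivars for one trait in one year, together with the percent
difference as printed in the trial report (reference cultivar in the
denominator, rounded half-up to 2 decimals). Only cells whose printed
difference reproduces exactly from the printed means are listed; cells
computed before rounding (or with an inconsistent denominator) are left
out.

These values serve as ground truth for round-trip demonstrations: they are
inputs to the pipeline, not outputs of it.
"""

#: (trait, year, mean_test, mean_reference, printed_difference_pct)
PRINTED_TRAIT_CELLS = [
    ("leaf_pn_hfs", 2011, 23.84, 20.98, 13.63),
    ("leaf_pn_ms", 2011, 20.00, 20.09, -0.45),
    ("leaf_pn_ds", 2011, 14.77, 14.98, -1.40),
    ("leaf_pn_ts", 2012, 23.24, 24.05, -3.37),
    ("leaf_pn_pds", 2012, 25.58, 21.31, 20.04),
    ("leaf_pn_hfs", 2012, 20.22, 18.16, 11.34),
    ("leaf_pn_ms", 2012, 20.10, 17.27, 16.39),
    ("leaf_pn_ds", 2012, 15.75, 14.27, 10.37),
    ("leaf_pn_ts", 2013, 26.70, 25.00, 6.80),
    ("leaf_pn_pds", 2014, 26.98, 25.32, 6.56),
    ("leaf_pn_hfs", 2014, 25.04, 24.77, 1.09),
    ("leaf_pn_ms", 2014, 21.51, 20.36, 5.65),
    ("asat_ts", 2015, 34.17, 31.00, 10.23),
    ("asat_lpds", 2015, 26.88, 25.30, 6.25),
    ("asat_ds", 2015, 13.30, 12.78, 4.07),
    ("asat_epds", 2016, 33.01, 28.78, 14.70),
    ("asat_lpds", 2016, 31.53, 29.17, 8.09),
    ("asat_ds", 2016, 15.87, 15.64, 1.47),
    ("pnmax_early_milk", 2013, 46.03, 39.72, 15.89),
    ("vcmax_milk", 2013, 105.91, 92.33, 14.71),
    ("jmax_milk", 2013, 191.66, 177.15, 8.19),
    ("grain_length", 2015, 9.32, 8.86, 5.19),
    ("grain_width", 2015, 2.63, 2.64, -0.38),
    ("grain_length_width_ratio", 2015, 3.57, 3.38, 5.62),
    ("grain_length", 2016, 9.50, 9.06, 4.86),
    ("grain_width", 2016, 2.56, 2.51, 1.99),
    ("grain_length_width_ratio", 2016, 3.74, 3.63, 3.03),
    ("grain_yield", 2011, 9.84, 9.36, 5.13),
    ("grain_yield", 2012, 11.62, 10.76, 7.99),
    ("grain_yield", 2013, 9.82, 9.09, 8.03),
    ("grain_yield", 2014, 10.20, 9.64, 5.81),
    ("grain_yield", 2016, 11.69, 11.08, 5.51),
]

#: Milk-stage flag-leaf fitted parameters of the test cultivar (mean values):
#: light response Pnmax 46.03, AQY 0.09; FvCB Vcmax 105.91, Jmax 191.66.
LIGHT_RESPONSE_TRUTH = {"pn_max": 46.03, "aqy": 0.09, "theta": 0.8, "rd": 2.0}
FVCB_TRUTH = {"vcmax": 105.91, "jmax": 191.66, "rd": 1.5}
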