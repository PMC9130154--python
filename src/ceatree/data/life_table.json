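{
  "description": "Synthetic period life table in the style of European (Eurostat) tables: remaining life expectancy by age. Anchored at 49.87 remaining years for a 30-year-old and 45.0 for a 35-year-old (mean age at death 80 for the modelled cohort); all other knots are plausible synthetic values, not published data.",
  "ages": [0, 10, 20, 25, 30, 35, 40, 45, 50, 55, 60, 65, 70, 75, 80, 85, 90, 95, 100],
  "remaining_years": [81.5, 71.8, 62.0, 55.9, 49.87, 45.0, 40.2, 35.5, 30.9, 26.4, 22.0, 17.8, 13.9, 10.4, 7.4, 5.0, 3.3, 2.1, 1.4]
}
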