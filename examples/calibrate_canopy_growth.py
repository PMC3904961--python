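"""Recover the canopy growth coefficient from noisy cover observations.

Simulates a season at the known parameters, samples the canopy-cover
trajectory every 10 days with 5%-cover Gaussian noise (the magnitude of
typical field CC errors), then calibrates cgc starting from a value 30%
too high.
"""

import dataclasses

import aquawheat as aw

TRUE_CGC = 0.03

weather = aw.gen_weather(aw.ClimateSpec(), season="2008", seed=7)
config = aw.ScenarioConfig(
    planting_date=aw.datasets.PLANTING_DATES["2008"][0], weather=weather,
    soil=aw.SoilProfile.xiaotangshan(), crop=aw.CropParams(cgc=TRUE_CGC),
    irrigation=aw.datasets.irrigation_schedule("2008"))
truth = aw.run_season(config)

obs = aw.gen_observations(
    truth, aw.ObservationSpec(days=list(range(10, 250, 10)), cc_noise_sd=5.0,
                              biomass_noise_sd=0.0), seed=1)

start = dataclasses.replace(config, crop=config.crop.replace(cgc=0.039))
res = aw.calibrate([(start, obs[["day", "cc_pct"]])], {"cgc": (0.01, 0.08)})

err = abs(res.fitted["cgc"] - TRUE_CGC) / TRUE_CGC * 100
print(f"true cgc      : {TRUE_CGC:.4f} /day")
print(f"start value   : 0.0390 /day (+30%)")
print(f"recovered cgc : {res.fitted['cgc']:.4f} /day  ({err:.1f}% off truth)")
print(f"fit RMSE      : {res.rmse:.2f} % cover over {len(obs)} observations")
print(f"simulator runs: {res.n_evals}")
print("\nThe growth rate is identifiable from a season of noisy cover data:")
print("the expansion phase pins cgc almost independently of the water terms.")
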