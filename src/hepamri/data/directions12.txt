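# 12 diffusion gradient directions (unit vectors): gx gy gz
# electrostatic-repulsion optimized with antipodal symmetry
-0.1604334870 0.9848484323 0.0658381470
-0.8492749414 0.5097341931 0.1374886404
-0.9543916471 -0.1755628330 0.2414834892
0.7480272005 0.6079289909 0.2662285659
-0.4388839075 -0.8310981840 0.3415504710
0.5481278334 -0.6957712177 0.4641748494
0.8275919295 -0.0419118431 0.5597633390
0.2098989470 0.7459816377 0.6320235979
-0.4508258512 0.5360605279 0.7137192461
-0.5559425569 -0.1492364981 0.8177140949
0.0099995799 -0.5577185709 0.8299698814
0.2282745350 0.1118384052 0.9671519569
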