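name,growth_form,unsampled_sa,tsa_sampled,esa_sampled,tsa_tissue,esa_tissue,tsa_skeleton,esa_skeleton,unsampled_v,tv_sampled,tv_tissue,tv_skeleton,tv_water
Platygyra daedalea,massive,381.50,394.58,351.33,93.22,47.26,93.68,48.39,664.18,616.28,43.79,40.39,27
Gardineroseris planulata,massive,2703.69,2587.70,2560.16,410.80,131.49,353.48,118.07,12978.50,12742.50,365.99,314.78,240
Porites lutea,massive,9821.73,9982.85,9927.23,153.12,89.41,150.17,87.45,101661.40,100402.00,129.62,126.91,84
Porites lobata,massive,18026.33,17911.17,17874.44,82.90,44.80,82.85,43.99,147841.20,146957.60,36.22,37.30,28
Pocillopora verrucosa,branched,874.50,816.93,744.30,347.13,344.93,285.63,269.00,1706.10,1198.70,69.03,73.69,55
Acropora 1,branched,1913.70,1715.42,1678.65,451.17,419.56,403.30,379.53,3138.20,2610.90,250.04,217.41,67
Acropora 2,branched,3196.79,3008.23,2942.44,158.21,151.87,137.31,130.34,6008.30,5075.40,30.37,30.06,19
Acropora hyacynthus,tabular,46686.73,45673.30,45673.30,379.47,372.89,304.47,298.31,,,84.72,83.26,21
Echinopora lamellosa,foliose,1350.82,1246.37,1246.37,191.17,90.62,195.32,95.11,,,32.52,30.91,33
Diploastrea heliopora,crustose,2685.03,2658.66,2577.36,293.61,52.91,271.47,48.90,4571.90,3980.60,179.47,174.46,127
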