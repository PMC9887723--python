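study,ppm,time_h,species,value_pmol_mm3,below_lod
Lu2011,0.7,7,endoDG,9.527e-4,false
Lu2011,0.7,7,exogDG,1.026e-5,false
Lu2011,2.0,7,endoDG,1.603e-3,false
Lu2011,2.0,7,exogDG,5.001e-5,false
Lu2011,5.8,7,endoDG,1.450e-3,false
Lu2011,5.8,7,exogDG,2.737e-4,false
Lu2011,9.1,7,endoDG,8.975e-4,false
Lu2011,9.1,7,exogDG,5.343e-4,false
Lu2011,15.2,7,endoDG,1.116e-3,false
Lu2011,15.2,7,exogDG,2.935e-3,false
Yu2015,2.0,175,endoDG,6.606e-4,false
Yu2015,2.0,175,exogDG,9.212e-5,false
Yu2015,2.0,343,endoDG,8.132e-4,false
Yu2015,2.0,343,exogDG,2.211e-4,false
Yu2015,2.0,511,endoDG,8.790e-4,false
Yu2015,2.0,511,exogDG,2.500e-4,false
Yu2015,2.0,679,endoDG,7.422e-4,false
Yu2015,2.0,679,exogDG,2.763e-4,false
Yu2015,2.0,684,endoDG,7.369e-4,false
Yu2015,2.0,684,exogDG,2.184e-4,false
Yu2015,2.0,702,endoDG,7.843e-4,false
Yu2015,2.0,702,exogDG,2.106e-4,false
Yu2015,2.0,750,endoDG,7.869e-4,false
Yu2015,2.0,750,exogDG,1.658e-4,false
Yu2015,2.0,846,endoDG,7.317e-4,false
Yu2015,2.0,846,exogDG,1.763e-4,false
Moeller2011,0.0,,endoDPC,1.711e-5,false
Moeller2011,2.0,178,endoDPC,1.258e-5,false
Moeller2011,2.0,178,exogDPC,2.527e-6,false
Moeller2011,2.0,192,endoDPC,1.187e-5,false
Moeller2011,2.0,192,exogDPC,6.474e-6,false
Moeller2011,2.0,696,endoDPC,9.948e-6,false
Moeller2011,2.0,696,exogDPC,5.580e-6,false
Moeller2011,2.0,840,endoDPC,9.238e-6,false
Moeller2011,2.0,840,exogDPC,5.632e-6,false
Moeller2011,15.0,24,endoDPC,1.163e-5,false
Moeller2011,15.0,24,exogDPC,1.453e-5,false
Moeller2011,15.0,48,endoDPC,1.126e-5,false
Moeller2011,15.0,48,exogDPC,1.234e-5,false
Moeller2011,15.0,96,endoDPC,9.659e-6,false
Moeller2011,15.0,96,exogDPC,4.785e-5,false
Leng2019,0.0,,endoDPC,7.001e-6,false
Leng2019,0.001,672,endoDPC,7.290e-6,false
Leng2019,0.001,672,exogDPC,,true
Leng2019,0.030,672,endoDPC,7.922e-6,false
Leng2019,0.030,672,exogDPC,,true
Leng2019,0.300,672,endoDPC,7.501e-6,false
Leng2019,0.300,672,exogDPC,,true
Casanova1989,0.32,6,exogDPX,5.74e-3,false
Casanova1994,0.72,1947,exogDPX,9.02e-3,false
Casanova1994,2.06,1947,exogDPX,2.42e-2,false
Casanova1994,6.01,1947,exogDPX,1.94e-1,false
Casanova1994,15.8,1947,exogDPX,1.14,false
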