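location_name,temperature_c,humidity_pct,wind_kmh,precip_mm_day,uv_index,soil_moisture_vwc,terrain
"Udaipur, Rajasthan",32,35,10,2,7,0.15,plain
"Raipur, Chattisgarh",28,65,8,12,6,0.35,plain
"Palampur, HP",22,60,12,8,5,0.25,hilly
"Anand, Gujarat",33,45,14,4,7,0.20,plain
"Jabalpur, MP",27,55,9,9,5,0.28,plain
"Faizabad, UP",25,50,7,6,5,0.22,plain
"Parbhani, Maharashtra",33,38,11,3,8,0.18,plain
"Anantapur, AP",34,30,13,2,9,0.12,plain
"Bangalore, Karnataka",27,55,10,5,6,0.20,plain
"Jammu, J&K",24,55,9,7,5,0.24,plain
"Hisar, Haryana",31,32,15,1,7,0.14,plain
"Ranchi, Jharkhand",26,70,8,14,5,0.32,hilly
"Ludhiana, Punjab",29,48,10,5,6,0.26,plain
"Thrissur, Kerala",31,85,12,25,5,0.45,plain
"Jorhat, Assam",28,82,6,20,4,0.40,plain
"Kanpur, UP",30,45,9,6,6,0.24,plain
"Dapoli, Maharashtra",29,80,14,22,5,0.42,hilly
"Bhubaneswar, Orissa",32,78,13,18,8,0.38,plain
"Mohanpur, UP",27,60,8,8,5,0.26,plain
"Kovilpatti, TN",33,72,16,12,9,0.33,plain
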