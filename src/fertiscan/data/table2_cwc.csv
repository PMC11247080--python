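district,crop
"Bangalore, Karnataka",Groundnut
"Hisar, Haryana",Mustard
"Bhubaneswar, Orissa",Rice
"Kanpur, UP",Rice
"Jabalpur, MP",Soybean
"Raipur, Chattisgarh",Wheat
"Udaipur, Rajasthan",Wheat
"Parbhani, Maharashtra",Cotton
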