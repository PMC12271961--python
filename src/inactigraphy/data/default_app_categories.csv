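app_id,category
google,A
com.google.android.googlequicksearchbox,A
firefox,A
chrome,A
duolingo,A
wikipedia,A
news,A
tagesschau,A
youtube,B
netflix,B
spotify,B
twitch,B
candycrush,B
minecraft,B
tiktok,B
kindle,B
clock,C
alarm,C
calculator,C
calendar,C
camera,C
notes,C
maps,C
weather,C
settings,C
email,C
facebook,D
whatsapp,D
instagram,D
telegram,D
signal,D
messenger,D
snapchat,D
discord,D
paypal,E
amazon,E
ebay,E
zalando,E
banking,E
sparkasse,E
trade republic,E
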